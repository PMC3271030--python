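"""Synthetic placebo-controlled cross-over studies with known ground truth.

The generator emulates the study design the health-space method targets:
every subject is measured under both a treated (active dietary mix) and a
control (placebo) arm, at several timepoints per period.  Parameters come in
named blocks — one per biological process (defaults: 7 oxidation,
18 inflammation, 115 metabolism parameters) — with equicorrelated noise
within a block, a per-subject random intercept shared across arms and
timepoints, and an additive treatment effect on affected parameters at
post-baseline timepoints of the treated arm.

Responder heterogeneity is planted through subgroups: each subject belongs
to one subgroup, and the treatment effect on block ``b`` for subject ``i``
is ``effect_size[b] * multiplier[subgroup(i), b]``.  The default two
subgroups mirror the qualitative pattern the method is meant to recover —
one group responding mainly on the inflammation and oxidation axes, the
other mainly on the metabolism axis.

Everything is driven by a single :class:`numpy.random.Generator` owned by
the call, so identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ARM_CONTROL, ARM_TREATED, AxisDefinition, SampleTable
from .exceptions import ConfigurationError

#: process blocks of the full axis configuration (parameter counts)
FULL_BLOCKS = {"oxidation": 7, "inflammation": 18, "metabolism": 115}
#: the same configuration with diet-derived parameters excluded
NO_DIET_BLOCKS = {"oxidation": 5, "inflammation": 15, "metabolism": 114}

BLOCK_PRESETS = {"full": FULL_BLOCKS, "no-diet": NO_DIET_BLOCKS}

DEFAULT_SUBGROUPS = (
    ("group1", 0.5, {"oxidation": 1.5, "inflammation": 1.5, "metabolism": 0.3}),
    ("group2", 0.5, {"oxidation": 0.3, "inflammation": 0.3, "metabolism": 1.5}),
)


@dataclass
class Subgroup:
    """A planted responder subgroup.

    ``multipliers`` scale the per-block treatment effect for members of this
    subgroup; blocks not listed default to 1.0.
    """

    label: str
    proportion: float
    multipliers: dict = field(default_factory=dict)

    def multiplier(self, block: str) -> float:
        return float(self.multipliers.get(block, 1.0))


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the simulated trial.

    Defaults describe a 33-subject double-blind placebo-controlled
    cross-over study with two timepoints per period, unit between-subject
    and residual noise, moderate within-block correlation (0.3) and a unit
    standardized treatment effect on every parameter (the axes of the
    method contain only parameters that responded to treatment, so all
    parameters carry an effect by default).
    """

    n_subjects: int = 33
    blocks: dict = field(default_factory=lambda: dict(FULL_BLOCKS))
    frac_affected: float | Mapping[str, float] = 1.0
    effect_size: float | Mapping[str, float] = 1.0
    subgroups: Sequence[Subgroup] = field(
        default_factory=lambda: [Subgroup(l, p, dict(m)) for l, p, m in DEFAULT_SUBGROUPS]
    )
    within_block_corr: float = 0.3
    subject_sd: float = 1.0
    noise_sd: float = 1.0
    n_timepoints: int = 2
    seed: int = 0

    # -- helpers ---------------------------------------------------------
    def _per_block(self, value, name: str) -> dict:
        if isinstance(value, Mapping):
            unknown = sorted(set(value) - set(self.blocks))
            if unknown:
                raise ConfigurationError(f"{name}: unknown blocks {unknown}")
            return {b: float(value.get(b, 1.0)) for b in self.blocks}
        return {b: float(value) for b in self.blocks}

    def effect_sizes(self) -> dict:
        return self._per_block(self.effect_size, "effect_size")

    def affected_fractions(self) -> dict:
        if isinstance(self.frac_affected, Mapping):
            return self._per_block(self.frac_affected, "frac_affected")
        return {b: float(self.frac_affected) for b in self.blocks}

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if not self.blocks or any(n < 1 for n in self.blocks.values()):
            raise ConfigurationError("blocks must map names to positive counts")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ConfigurationError("within_block_corr must lie in [0, 1)")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("scales must be >= 0")
        if self.n_timepoints < 1:
            raise ConfigurationError("n_timepoints must be >= 1")
        for frac in self.affected_fractions().values():
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError("frac_affected must lie in [0, 1]")
        total = sum(g.proportion for g in self.subgroups)
        if not self.subgroups or not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(
                f"subgroup proportions must sum to 1 (got {total})"
            )

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["subgroups"] = [asdict(g) for g in self.subgroups]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "subgroups" in d:
            groups = []
            for g in d["subgroups"]:
                if isinstance(g, Subgroup):
                    groups.append(g)
                elif isinstance(g, Mapping):
                    groups.append(
                        Subgroup(
                            label=str(g["label"]),
                            proportion=float(g["proportion"]),
                            multipliers=dict(g.get("multipliers", {})),
                        )
                    )
                else:  # (label, proportion, multipliers) tuple
                    label, prop, mult = g
                    groups.append(Subgroup(str(label), float(prop), dict(mult)))
            d["subgroups"] = groups
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation settings: {sorted(unknown)}")
        return cls(**d)


def parameter_names(blocks: Mapping[str, int]) -> dict:
    """Deterministic parameter naming: ``{block}_{001}`` ... per block."""
    return {
        block: [f"{block}_{i + 1:03d}" for i in range(int(n))]
        for block, n in blocks.items()
    }


def generate_study(config: SimulationConfig) -> tuple[SampleTable, dict]:
    """Simulate one cross-over study; return the table and its ground truth.

    The value of parameter ``j`` for subject ``i``, arm ``a``, timepoint
    ``t`` is::

        b_ij + eps_ijat + 1[a = treated, j affected, t > t0] * d_b * m_ib

    where ``b_ij ~ N(0, subject_sd^2)`` is a subject-parameter intercept
    shared across arms/timepoints, ``eps`` is equicorrelated within-block
    Gaussian noise with scale ``noise_sd``, ``d_b`` the block effect size
    and ``m_ib`` the subject's subgroup multiplier for the block.

    The truth record holds each subject's subgroup label and each
    parameter's affected flag.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    names = parameter_names(config.blocks)
    all_params = [p for block in config.blocks for p in names[block]]
    block_of = {p: b for b in config.blocks for p in names[b]}
    n_params = len(all_params)

    subjects = [f"s{i + 1:02d}" for i in range(config.n_subjects)]

    # subgroup assignment: largest-remainder apportionment, then shuffled
    props = [g.proportion for g in config.subgroups]
    counts = [int(math.floor(p * config.n_subjects)) for p in props]
    remainders = [p * config.n_subjects - c for p, c in zip(props, counts)]
    for k in np.argsort(remainders)[::-1][: config.n_subjects - sum(counts)]:
        counts[int(k)] += 1
    labels = [g.label for g, c in zip(config.subgroups, counts) for _ in range(c)]
    labels = list(np.asarray(labels)[rng.permutation(config.n_subjects)])
    subgroup_of = dict(zip(subjects, labels))
    group_by_label = {g.label: g for g in config.subgroups}

    # affected parameters: a deterministic count per block, chosen at random
    fracs = config.affected_fractions()
    affected: dict[str, bool] = {p: False for p in all_params}
    for block, plist in names.items():
        n_aff = int(round(fracs[block] * len(plist)))
        chosen = rng.choice(len(plist), size=n_aff, replace=False)
        for k in chosen:
            affected[plist[int(k)]] = True

    effects = config.effect_sizes()
    timepoints = [f"t{t}" for t in range(config.n_timepoints)]

    intercepts = rng.normal(0.0, config.subject_sd, size=(config.n_subjects, n_params))

    rho = config.within_block_corr
    rows = []
    meta_rows = []
    for i, subject in enumerate(subjects):
        group = group_by_label[subgroup_of[subject]]
        for arm in (ARM_TREATED, ARM_CONTROL):
            for t, tp in enumerate(timepoints):
                # equicorrelated block noise via a shared block factor
                eps = np.empty(n_params)
                offset = 0
                for block, plist in names.items():
                    nb = len(plist)
                    shared = rng.normal()
                    indiv = rng.normal(size=nb)
                    eps[offset : offset + nb] = config.noise_sd * (
                        math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * indiv
                    )
                    offset += nb
                value = intercepts[i] + eps
                if arm == ARM_TREATED and t > 0:
                    for j, p in enumerate(all_params):
                        if affected[p]:
                            b = block_of[p]
                            value[j] += effects[b] * group.multiplier(b)
                rows.append(value)
                meta_rows.append((subject, arm, tp))

    values = pd.DataFrame(np.asarray(rows), columns=all_params)
    meta = pd.DataFrame(meta_rows, columns=["subject_id", "arm", "timepoint"])
    table = SampleTable(values, meta)
    truth = {
        "subgroup": subgroup_of,
        "affected": affected,
        "effect_sizes": effects,
        "blocks": {b: list(plist) for b, plist in names.items()},
        "seed": config.seed,
    }
    return table, truth


def default_axes(
    config: SimulationConfig,
    blocks: Sequence[str] | None = None,
    kind: str = "mean_over_time",
) -> list[AxisDefinition]:
    """One axis per process block of ``config``.

    By default each parameter contributes a single ``mean_over_time``
    feature, so the feature count per axis equals the block's parameter
    count (7 / 18 / 115 under the full preset, 5 / 15 / 114 without
    diet-derived parameters).  ``kind="both"`` instead emits a baseline plus
    a mean-over-time feature per parameter.
    """
    names = parameter_names(config.blocks)
    selected = list(config.blocks) if blocks is None else list(blocks)
    unknown = sorted(set(selected) - set(config.blocks))
    if unknown:
        raise ConfigurationError(f"unknown blocks {unknown}")
    axes = []
    for block in selected:
        if kind == "both":
            feats = [(p, k) for p in names[block] for k in ("baseline", "mean_over_time")]
        else:
            feats = [(p, kind) for p in names[block]]
        axes.append(AxisDefinition(axis_name=block, features=tuple(feats)))
    return axes


def preset_config(name: str = "full", **overrides) -> SimulationConfig:
    """A :class:`SimulationConfig` whose blocks follow a named preset."""
    if name not in BLOCK_PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(BLOCK_PRESETS)}"
        )
    cfg = SimulationConfig(blocks=dict(BLOCK_PRESETS[name]), **overrides)
    cfg.validate()
    return cfg


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
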