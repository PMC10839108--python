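"""Synthetic cohorts with a known hierarchical variance structure.

The generator draws per-farm, per-batch, and farm-by-batch effects plus a
pig-level residual so that each component carries a prescribed fraction of
the total variance. Two noise families are supported:

``additive_gaussian``
    hcc = grand_mean + F_farm + B_batch + I_(farm,batch) + eps, every
    component mean-zero Gaussian with variance = fraction * total_sd**2.
    Expected sums of squares then have closed forms, which the tests use.

``lognormal``
    The same linear predictor built on the log scale with moment-matched
    parameters, so the realized arithmetic mean/SD approximate the targets
    while producing right skew and a positive coupling between batch means
    and batch SDs. Matching is approximate by construction; equality
    assertions belong to the additive family only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from cortivar.cohort import Cohort, PigRecord

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_cohort",
    "emulate_study_design",
    "STUDY_FRACTIONS",
]

#: Variance fractions calibrated to the reference 20-farm field study.
STUDY_FRACTIONS = {"farm": 0.241, "interaction": 0.163, "batch": 0.031, "residual": 0.565}

_COMPONENTS = ("farm", "batch", "interaction", "residual")


@dataclass(frozen=True)
class SimulationParams:
    """Design and distributional parameters of a synthetic cohort."""

    n_farms: int = 20
    n_batches_per_farm: int = 2
    n_pigs_per_batch: int = 24
    grand_mean: float = 25.9
    total_sd: float = 16.2
    variance_fractions: dict[str, float] = field(
        default_factory=lambda: dict(STUDY_FRACTIONS)
    )
    noise_family: str = "additive_gaussian"
    dropout: tuple[tuple[int, int, int], ...] = ()
    detection_floor: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_family not in ("additive_gaussian", "lognormal"):
            raise ValueError(f"unknown noise_family {self.noise_family!r}")
        if self.grand_mean <= 0:
            raise ValueError("grand_mean must be > 0")
        if self.total_sd <= 0:
            raise ValueError("total_sd must be > 0")
        missing = [c for c in _COMPONENTS if c not in self.variance_fractions]
        if missing:
            raise ValueError(f"variance_fractions missing components {missing}")
        vals = [self.variance_fractions[c] for c in _COMPONENTS]
        if any(v < 0 for v in vals):
            raise ValueError("variance fractions must be >= 0")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"variance fractions must sum to 1, got {sum(vals)}")


@dataclass
class GroundTruth:
    """Realized effects and generating parameters behind a synthetic cohort."""

    params: SimulationParams
    farm_effects: dict[str, float]
    batch_effects: dict[str, float]
    interaction_effects: dict[tuple[str, str], float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "variance_fractions": self.params.variance_fractions,
                "grand_mean": self.params.grand_mean,
                "total_sd": self.params.total_sd,
                "noise_family": self.params.noise_family,
                "seed": self.params.seed,
                "farm_effects": self.farm_effects,
                "batch_effects": self.batch_effects,
                "interaction_effects": {
                    f"{f}|{b}": v for (f, b), v in self.interaction_effects.items()
                },
            },
            indent=2,
            sort_keys=True,
        )


def _farm_label(i: int) -> str:
    # A..Z then F26, F27, ... to stay readable at any design size
    return chr(ord("A") + i) if i < 26 else f"F{i}"


def generate_cohort(params: SimulationParams) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort from ``params``; fully reproducible from ``params.seed``.

    Returns the cohort plus the realized farm/batch/interaction effects
    (on the generating scale: raw pg/mg for the additive family, log scale
    for the lognormal family).
    """
    rng = np.random.default_rng(params.seed)
    fracs = params.variance_fractions
    K, B, P = params.n_farms, params.n_batches_per_farm, params.n_pigs_per_batch

    if params.noise_family == "additive_gaussian":
        mu, total_var = params.grand_mean, params.total_sd**2
    else:
        # moment matching: target arithmetic mean/SD -> log-scale mu, sigma^2
        total_var = math.log1p((params.total_sd / params.grand_mean) ** 2)
        mu = math.log(params.grand_mean) - total_var / 2.0

    def scaled(draw: np.ndarray, frac: float) -> np.ndarray:
        # center and rescale so the realized population variance is exact;
        # this makes the sequential eta-squared recover the fractions
        # instead of only approximating them at small level counts
        if frac == 0.0 or draw.size < 2:
            return np.zeros_like(draw)
        centered = draw - draw.mean()
        sd = centered.std(ddof=0)
        if sd == 0:
            return np.zeros_like(draw)
        return centered * (math.sqrt(frac * total_var) / sd)

    farms = [_farm_label(i) for i in range(K)]
    batches = [str(b + 1) for b in range(B)]

    farm_vec = scaled(rng.normal(size=K), fracs["farm"])
    batch_vec = scaled(rng.normal(size=B), fracs["batch"])
    # interaction: double-center the K x B draw so it is orthogonal to the
    # farm and batch main effects, then rescale to its exact variance share
    inter = rng.normal(size=(K, B))
    inter = inter - inter.mean(axis=1, keepdims=True) - inter.mean(axis=0, keepdims=True) + inter.mean()
    if fracs["interaction"] == 0.0 or inter.std(ddof=0) == 0:
        inter = np.zeros_like(inter)
    else:
        inter *= math.sqrt(fracs["interaction"] * total_var) / inter.std(ddof=0)

    farm_eff = dict(zip(farms, farm_vec))
    batch_eff = dict(zip(batches, batch_vec))
    inter_eff = {(f, b): inter[fi, bi] for fi, f in enumerate(farms) for bi, b in enumerate(batches)}

    drop: dict[tuple[int, int], int] = {}
    for fi, bi, count in params.dropout:
        if not (0 <= fi < K and 0 <= bi < B):
            raise ValueError(f"dropout cell ({fi}, {bi}) outside the design")
        if count >= P:
            raise ValueError(f"dropout of {count} exceeds cell size {P}")
        drop[(fi, bi)] = drop.get((fi, bi), 0) + count

    eps_all = rng.normal(size=(K, B, P))
    eps_all = scaled(eps_all.ravel(), fracs["residual"]).reshape(K, B, P)

    records: list[PigRecord] = []
    for fi, f in enumerate(farms):
        for bi, b in enumerate(batches):
            n = P - drop.get((fi, bi), 0)
            lin = mu + farm_eff[f] + batch_eff[b] + inter_eff[(f, b)] + eps_all[fi, bi, :n]
            hcc = np.exp(lin) if params.noise_family == "lognormal" else lin
            if params.detection_floor is not None:
                hcc = np.maximum(hcc, params.detection_floor)
            # the additive family can stray below zero in extreme tails;
            # clip to a hair above zero to honour the hcc > 0 invariant
            hcc = np.maximum(hcc, 1e-6)
            records.extend(
                PigRecord(farm_id=f, batch_id=b, pig_id=f"{f}{b}-{p + 1:03d}", hcc=float(v))
                for p, v in enumerate(hcc)
            )

    truth = GroundTruth(
        params=params,
        farm_effects={k: float(v) for k, v in farm_eff.items()},
        batch_effects={k: float(v) for k, v in batch_eff.items()},
        interaction_effects={k: float(v) for k, v in inter_eff.items()},
    )
    return Cohort(records), truth


def emulate_study_design(seed: int = 0, **overrides) -> Cohort:
    """A cohort shaped like the reference field study.

    20 farms x 2 batches x 24 pigs, minus 10 pigs removed as 2 each from 5
    distinct (farm, batch) cells chosen by ``seed``; lognormal family with
    study-calibrated mean, SD and variance fractions. Always 950 records.
    """
    rng = np.random.default_rng(seed)
    n_farms, n_batches = overrides.get("n_farms", 20), overrides.get("n_batches_per_farm", 2)
    cells = [(f, b) for f in range(n_farms) for b in range(n_batches)]
    chosen = rng.choice(len(cells), size=5, replace=False)
    dropout = tuple((*cells[i], 2) for i in sorted(chosen))
    params = SimulationParams(
        noise_family=overrides.get("noise_family", "lognormal"),
        dropout=dropout,
        seed=seed,
        **{k: v for k, v in overrides.items() if k not in ("noise_family",)},
    )
    cohort, _ = generate_cohort(params)
    return cohort
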