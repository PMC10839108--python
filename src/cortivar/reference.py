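"""Bundled reference data: per-batch HCC summary statistics from a published
20-farm finishing-pig field study (two batches per farm, 24 pigs sampled per
batch), used as a worked example and as validation input for the typology
and effect-size routines.

Values are as printed (1 decimal, pg/mg): farm -> (mean and SD of batch 1,
mean and SD of batch 2).
"""

from __future__ import annotations

from cortivar.cohort import BatchSummary

__all__ = ["FIELD_STUDY_TABLE", "field_study_summaries", "PIGS_PER_BATCH"]

PIGS_PER_BATCH = 24

#: farm -> (mean_b1, sd_b1, mean_b2, sd_b2) in pg/mg
FIELD_STUDY_TABLE: dict[str, tuple[float, float, float, float]] = {
    "A": (4.9, 1.6, 13.7, 6.1),
    "B": (4.8, 3.1, 6.5, 1.7),
    "C": (35.9, 25.7, 42.5, 15.2),
    "D": (13.6, 8.3, 34.0, 18.0),
    "E": (13.7, 3.7, 54.5, 24.1),
    "F": (24.5, 6.0, 32.0, 13.2),
    "G": (15.6, 4.7, 13.8, 3.7),
    "H": (17.6, 5.5, 25.0, 14.3),
    "I": (20.3, 3.6, 32.6, 21.1),
    "J": (36.5, 9.7, 18.4, 7.5),
    "K": (11.3, 3.6, 29.6, 11.8),
    "L": (30.2, 9.1, 26.5, 8.8),
    "M": (29.7, 7.1, 24.6, 10.4),
    "N": (26.9, 12.6, 28.6, 6.0),
    "O": (29.5, 8.8, 43.8, 24.5),
    "P": (31.8, 13.7, 29.2, 15.1),
    "Q": (37.1, 21.2, 16.6, 4.8),
    "R": (21.3, 12.4, 29.4, 9.9),
    "S": (27.2, 11.8, 37.4, 15.0),
    "T": (25.0, 9.0, 33.9, 12.9),
}


#: Published absolute Cohen's d per farm (combined-sample convention).
FIELD_STUDY_COHENS_D: dict[str, float] = {
    "A": 1.4, "B": 0.7, "C": 0.3, "D": 1.2, "E": 1.5, "F": 0.7, "G": 0.4,
    "H": 0.7, "I": 0.8, "J": 1.4, "K": 1.4, "L": 0.4, "M": 0.6, "N": 0.2,
    "O": 0.7, "P": 0.2, "Q": 1.1, "R": 0.7, "S": 0.7, "T": 0.6,
}

#: Farms reported with a significant within-farm batch difference, by level.
FIELD_STUDY_SIGNIFICANT = {
    "p<0.001": ("D", "E", "J", "K", "Q"),
    "p<0.05": ("O",),
}


def field_study_summaries(n: int = PIGS_PER_BATCH) -> list[BatchSummary]:
    """The reference table as :class:`BatchSummary` rows (n pigs per batch)."""
    out = []
    for farm, (m1, s1, m2, s2) in sorted(FIELD_STUDY_TABLE.items()):
        out.append(BatchSummary(farm_id=farm, batch_id="1", n=n, mean=m1, sd=s1))
        out.append(BatchSummary(farm_id=farm, batch_id="2", n=n, mean=m2, sd=s2))
    return out


def field_study_cohort(seed: int = 0) -> "Cohort":
    """A pig-level cohort whose per-cell moments reproduce the reference table.

    Each (farm, batch) cell holds 24 right-skewed draws affinely rescaled so
    that its sample mean and SD equal the printed values exactly (to float
    precision). Pig-level detail beyond the first two moments is synthetic,
    so only statistics that are functions of the per-cell summaries are
    faithful to the source study.
    """
    import numpy as np

    from cortivar.cohort import Cohort, PigRecord

    rng = np.random.default_rng(seed)
    records = []
    for farm, (m1, s1, m2, s2) in sorted(FIELD_STUDY_TABLE.items()):
        for batch, (m, s) in (("1", (m1, s1)), ("2", (m2, s2))):
            # gamma(0.5) keeps the standardized minimum shallow enough that
            # every rescaled cell stays strictly positive; redraw in the
            # (rare) case a cell still crosses zero
            for _ in range(100):
                z = rng.gamma(0.5, size=PIGS_PER_BATCH)
                x = m + s * (z - z.mean()) / z.std(ddof=1)
                if np.all(x > 0):
                    break
            else:  # pragma: no cover
                raise RuntimeError(f"could not realize positive cell ({farm}, {batch})")
            records.extend(
                PigRecord(farm_id=farm, batch_id=batch, pig_id=f"{farm}{batch}-{i+1:02d}", hcc=float(v))
                for i, v in enumerate(x)
            )
    return Cohort(records)
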