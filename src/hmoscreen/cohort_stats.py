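"""Cohort-level gene-trait statistics.

Prevalence (carriers / cohort, with round-half-up integer percent, the
convention of the source prevalence tables), sequence conservation (mean
and sample SD of best-hit identity over carriers), Welch two-sample
comparisons of growth between genotype groups, and prediction/observation
concordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .growth import GrowthRecord
from .rules import PredictionRecord


class CohortStatsError(ValueError):
    pass


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PrevalenceResult:
    gene_id: str
    species: str | None
    carrier_count: int
    cohort_size: int

    @property
    def prevalence_exact(self) -> float:
        return 100.0 * self.carrier_count / self.cohort_size

    @property
    def prevalence_pct(self) -> int:
        return _round_half_up(self.prevalence_exact)


@dataclass(frozen=True)
class ConservationResult:
    gene_id: str
    n_carriers: int
    identity_mean: float
    identity_sd: float
    sd_defined: bool


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    welch_t: float
    welch_df: float
    p_two_sided: float
    unit: str = "OD600 delta"


@dataclass(frozen=True)
class ConcordanceResult:
    per_substrate: Mapping[str, Mapping[str, int]]  # substrate -> TP/FP/FN/TN
    discordant: tuple[tuple[str, str, str], ...]  # (strain, substrate, kind)

    @property
    def totals(self) -> dict[str, int]:
        out = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
        for counts in self.per_substrate.values():
            for k in out:
                out[k] += counts[k]
        return out

    @property
    def agreement_pct(self) -> float:
        t = self.totals
        total = sum(t.values())
        return 100.0 * (t["TP"] + t["TN"]) / total if total else float("nan")


def prevalence(
    presence_by_strain: Mapping[str, Mapping[str, bool]],
    gene_id: str,
    species_by_strain: Mapping[str, str] | None = None,
    species: str | None = None,
) -> PrevalenceResult:
    """Carrier count / cohort size for one gene, optionally filtered to a
    species. Raises on an empty cohort after filtering."""
    strains = list(presence_by_strain)
    if species is not None:
        if species_by_strain is None:
            raise CohortStatsError("species filter requires species mapping")
        strains = [s for s in strains if species_by_strain.get(s) == species]
    if not strains:
        raise CohortStatsError(
            f"empty cohort for species filter {species!r}"
        )
    carriers = sum(
        1 for s in strains if presence_by_strain[s].get(gene_id, False)
    )
    return PrevalenceResult(
        gene_id=gene_id, species=species,
        carrier_count=carriers, cohort_size=len(strains),
    )


def conservation(
    identity_by_strain: Mapping[str, float | None], gene_id: str = ""
) -> ConservationResult:
    """Mean and sample SD (n-1) of best-hit identity over carriers only.

    ``identity_by_strain`` maps strain -> best-hit identity_pct, or None /
    missing for non-carriers. A single carrier reports SD 0.0 with
    ``sd_defined=False``.
    """
    values = [v for v in identity_by_strain.values() if v is not None]
    if not values:
        raise CohortStatsError(
            f"conservation undefined: no carriers for {gene_id!r}"
        )
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if arr.size == 1:
        return ConservationResult(gene_id, 1, mean, 0.0, False)
    return ConservationResult(
        gene_id, int(arr.size), mean, float(arr.std(ddof=1)), True
    )


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch unequal-variance t statistic, Welch-Satterthwaite df, and the
    two-sided p-value from the t distribution."""
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise CohortStatsError(
            "Welch comparison needs >= 2 observations per group"
        )
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    na, nb = xa.size, xb.size
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = float((xa.mean() - xb.mean()) / math.sqrt(se2))
    df = float(
        se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    )
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def compare_groups(
    growth_records: Sequence[GrowthRecord],
    in_group_a: Callable[[str], bool],
    substrate: str,
    level: str = "strain",
    label_a: str = "group_a",
    label_b: str = "group_b",
) -> GroupComparison:
    """Welch comparison of growth on one substrate between two strain
    groups defined by a genotype predicate on the strain id.

    ``level="strain"`` compares per-strain delta OD (the default);
    ``level="replicate"`` compares individual blank-corrected wells.
    """
    if level not in ("strain", "replicate"):
        raise CohortStatsError(f"unknown comparison level {level!r}")
    a: list[float] = []
    b: list[float] = []
    for rec in growth_records:
        if rec.substrate != substrate:
            continue
        if level == "strain":
            values = [rec.delta_od]
        else:
            values = [max(od - rec.blank_od, 0.0) for od in rec.replicate_ods]
        (a if in_group_a(rec.strain_id) else b).extend(values)
    if not a or not b:
        raise CohortStatsError(
            f"both groups must be nonempty for substrate {substrate!r}"
        )
    t, df, p = welch_t_test(a, b)
    xa, xb = np.asarray(a), np.asarray(b)
    return GroupComparison(
        label_a=label_a, label_b=label_b,
        n_a=xa.size, n_b=xb.size,
        mean_a=float(xa.mean()), mean_b=float(xb.mean()),
        sd_a=float(xa.std(ddof=1)), sd_b=float(xb.std(ddof=1)),
        welch_t=t, welch_df=df, p_two_sided=p,
    )


def concordance(
    predictions: Sequence[PredictionRecord],
    growth_records: Sequence[GrowthRecord],
    growth_call: Callable[[GrowthRecord], bool] = lambda r: r.category != "none",
) -> ConcordanceResult:
    """Confusion counts per substrate between predicted growth and the
    observed growth call (default: any non-"none" category is growth)."""
    if not predictions:
        raise CohortStatsError("empty prediction set")
    observed = {
        (r.strain_id, r.substrate): growth_call(r) for r in growth_records
    }
    per_substrate: dict[str, dict[str, int]] = {}
    discordant: list[tuple[str, str, str]] = []
    for pred in predictions:
        key = (pred.strain_id, pred.substrate)
        if key not in observed:
            raise CohortStatsError(
                f"no growth record for strain {pred.strain_id!r} on "
                f"{pred.substrate!r}"
            )
        grew = observed[key]
        predicted_growth = pred.predicted == "growth"
        counts = per_substrate.setdefault(
            pred.substrate, {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
        )
        if predicted_growth and grew:
            counts["TP"] += 1
        elif predicted_growth and not grew:
            counts["FP"] += 1
            discordant.append((pred.strain_id, pred.substrate, "FP"))
        elif not predicted_growth and grew:
            counts["FN"] += 1
            discordant.append((pred.strain_id, pred.substrate, "FN"))
        else:
            counts["TN"] += 1
    return ConcordanceResult(
        per_substrate=per_substrate, discordant=tuple(discordant)
    )
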