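"""Splicing-sensitive expression readouts for intron-deletion mutants.

A splicing-sensitive microarray carries three probe classes per
intron-containing gene: intron (pre-mRNA), junction (mature mRNA) and exon
(total mRNA).  Replicate-averaged log2(mutant/wild-type) ratios of these
probes quantify the effect of deleting an intron (a "Δi" mutant).  The
Intron Accumulation Index change — intron minus exon log2 change — tracks
the pre-mRNA:total ratio and rises when splicing of the measured gene
becomes less efficient, the hallmark of negative feedback acting through
splicing inhibition.

Gene-level changes are read against the distribution of all changes on the
array using boxplot conventions: values beyond 1.5 interquartile ranges
from the quartiles are outliers.

qPCR quantification goes through per-primer calibration curves (Cq vs
log10 template), with curves of r^2 < 0.96 excluded; target quantities are
referenced to a housekeeping gene and expressed as log2 ratios relative to
the wild-type baseline.  Transcript accounting converts per-copy relative
changes into percent-of-wild-type totals by weighting with each copy's
wild-type share of the transcript pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

OUTLIER_UP = "OUTLIER_UP"
UP = "UP"
DOWN = "DOWN"
OUTLIER_DOWN = "OUTLIER_DOWN"
NONE = "NONE"

#: calibration curves below this coefficient of determination are unusable
MIN_CALIBRATION_R2 = 0.96


@dataclass(frozen=True)
class ProbeTriplet:
    gene_id: str
    mutant_id: str
    log2_change_intron: float | None
    log2_change_junction: float | None
    log2_change_exon: float
    n_replicates: int


@dataclass(frozen=True)
class IAIChange:
    gene_id: str
    mutant_id: str
    delta_iai: float


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def usable(self) -> bool:
        return self.slope < 0 and self.r_squared >= MIN_CALIBRATION_R2


@dataclass(frozen=True)
class RelativeExpression:
    gene_id: str
    mutant_id: str
    log2_ratios: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.log2_ratios))


@dataclass(frozen=True)
class TranscriptShare:
    share_a: float
    share_b: float
    fold_a: float
    fold_b: float

    @property
    def percent_a(self) -> float:
        return self.share_a * self.fold_a

    @property
    def percent_b(self) -> float:
        return self.share_b * self.fold_b

    @property
    def total_percent(self) -> float:
        return self.percent_a + self.percent_b


def expression_change(gene_id: str, mutant_id: str,
                      replicates: Mapping[str, Sequence[float]],
                      ) -> ProbeTriplet:
    """Replicate-averaged log2 changes per probe class.

    ``replicates`` maps probe class ("intron", "junction", "exon") to the
    per-array log2 ratios; every supplied class needs >= 2 replicates.
    """
    means: dict[str, float | None] = {}
    n_min = None
    for cls in ("intron", "junction", "exon"):
        vals = replicates.get(cls)
        if vals is None:
            means[cls] = None
            continue
        if len(vals) < 2:
            raise ValueError(
                f"{gene_id}/{mutant_id}: probe class {cls!r} has "
                f"{len(vals)} replicate(s); >= 2 required")
        means[cls] = float(np.mean(vals))
        n_min = len(vals) if n_min is None else min(n_min, len(vals))
    if means["exon"] is None:
        raise ValueError(f"{gene_id}/{mutant_id}: exon probes required")
    return ProbeTriplet(gene_id, mutant_id, means["intron"],
                        means["junction"], means["exon"], n_min or 0)


def intron_accumulation_index(triplet: ProbeTriplet) -> IAIChange | None:
    """Change in pre-mRNA:total mRNA ratio, as intron - exon log2 change.

    Positive values mean the gene's intron accumulates relative to total
    message — splicing has become less efficient.  None when the gene has
    no intron probe (intronless genes have no index).
    """
    if triplet.log2_change_intron is None:
        return None
    return IAIChange(triplet.gene_id, triplet.mutant_id,
                     triplet.log2_change_intron - triplet.log2_change_exon)


def classify_against_population(value: float,
                                population: Sequence[float]) -> str:
    """Place a gene's change against the array-wide boxplot.

    Whiskers sit at 1.5 interquartile ranges beyond the quartiles
    (linear-interpolation convention); values beyond them are outliers,
    values exactly on a whisker are inside.  Inside the whiskers the call
    is UP/DOWN relative to the median, NONE at the median exactly.
    """
    pop = np.asarray(population, dtype=float)
    if pop.size < 4:
        raise ValueError("population must have >= 4 values")
    q1, med, q3 = np.percentile(pop, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    if value > hi:
        return OUTLIER_UP
    if value < lo:
        return OUTLIER_DOWN
    if value > med:
        return UP
    if value < med:
        return DOWN
    return NONE


def fit_calibration(dilution_series: Sequence[tuple[float, float]],
                    ) -> CalibrationCurve:
    """Least-squares line of Cq on log10(template amount).

    Needs >= 3 points spanning >= 2 log10 units.  A non-monotone series
    still fits; it simply lands below the r^2 cutoff and is excluded via
    the ``usable`` flag.
    """
    if len(dilution_series) < 3:
        raise ValueError("calibration needs >= 3 dilution points")
    amounts = np.array([a for a, _ in dilution_series], dtype=float)
    cqs = np.array([c for _, c in dilution_series], dtype=float)
    if np.any(amounts <= 0):
        raise ValueError("template amounts must be positive")
    logs = np.log10(amounts)
    if logs.max() - logs.min() < 2.0:
        raise ValueError("dilution series must span >= 2 log10 units")
    fit = stats.linregress(logs, cqs)
    return CalibrationCurve(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue) ** 2)


def quantity_from_cq(curve: CalibrationCurve, cq: float) -> float:
    """Invert a calibration curve: template amount for an observed Cq."""
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def relative_quantity(gene_id: str, mutant_id: str,
                      target_cq: Mapping[str, Sequence[float]],
                      reference_cq: Mapping[str, Sequence[float]],
                      wt_target_cq: Mapping[str, Sequence[float]],
                      wt_reference_cq: Mapping[str, Sequence[float]],
                      target_curve: CalibrationCurve,
                      reference_curve: CalibrationCurve,
                      ) -> RelativeExpression:
    """Standard-curve relative quantification against a reference gene.

    Inputs map biological replicate id -> technical-replicate Cq values.
    Technical replicates collapse to a median Cq; quantities come from the
    primer's calibration curve; target/reference ratios are log2-ed and
    re-expressed relative to the mean wild-type log2 ratio.
    """
    for curve, name in ((target_curve, "target"),
                        (reference_curve, "reference")):
        if not curve.usable:
            raise ValueError(f"{name} calibration curve unusable "
                             f"(r^2={curve.r_squared:.3f})")

    def log2_ratios(tgt, ref):
        out = []
        for rep in sorted(tgt):
            cq_t = float(np.median(tgt[rep]))
            cq_r = float(np.median(ref[rep]))
            q_t = quantity_from_cq(target_curve, cq_t)
            q_r = quantity_from_cq(reference_curve, cq_r)
            out.append(np.log2(q_t / q_r))
        return out

    wt = log2_ratios(wt_target_cq, wt_reference_cq)
    baseline = float(np.mean(wt))
    mut = [r - baseline for r in log2_ratios(target_cq, reference_cq)]
    return RelativeExpression(gene_id, mutant_id, tuple(mut))


def summarize_probe_table(probe_table) -> "pd.DataFrame":
    """Collapse a long probe table to per-gene/mutant triplets and IAI.

    Input columns: gene_id, mutant_id, probe_class, replicate, log2_ratio.
    Output: one row per (gene_id, mutant_id) with replicate-averaged log2
    changes per probe class and the Intron Accumulation Index change.
    """
    import pandas as pd

    rows = []
    for (gene, mutant), grp in probe_table.groupby(["gene_id", "mutant_id"]):
        reps = {cls: list(sub.log2_ratio)
                for cls, sub in grp.groupby("probe_class")}
        triplet = expression_change(gene, mutant, reps)
        iai = intron_accumulation_index(triplet)
        rows.append({
            "gene_id": gene, "mutant_id": mutant,
            "log2_change_intron": triplet.log2_change_intron,
            "log2_change_junction": triplet.log2_change_junction,
            "log2_change_exon": triplet.log2_change_exon,
            "delta_iai": None if iai is None else iai.delta_iai,
            "n_replicates": triplet.n_replicates})
    return pd.DataFrame(rows)


def relative_quantity_from_tables(qpcr_table, dilution_table,
                                  gene_id: str, mutant_id: str,
                                  reference: str = "SCR1",
                                  wild_type: str = "wt",
                                  ) -> RelativeExpression:
    """Run the qPCR chain from long-format tables.

    ``qpcr_table`` has columns primer, sample, bio_rep, tech_rep, Cq;
    ``dilution_table`` has primer, amount_ng, Cq.  Curves are fit per
    primer and the relative quantity of ``gene_id`` in ``mutant_id`` is
    computed against ``reference`` and the wild-type baseline.
    """
    def curve(primer):
        sub = dilution_table[dilution_table.primer == primer]
        return fit_calibration(list(zip(sub.amount_ng, sub.Cq)))

    def cq_sets(primer, sample):
        sub = qpcr_table[(qpcr_table.primer == primer)
                         & (qpcr_table["sample"] == sample)]
        return {rep: list(grp.Cq) for rep, grp in sub.groupby("bio_rep")}

    return relative_quantity(
        gene_id, mutant_id,
        target_cq=cq_sets(gene_id, mutant_id),
        reference_cq=cq_sets(reference, mutant_id),
        wt_target_cq=cq_sets(gene_id, wild_type),
        wt_reference_cq=cq_sets(reference, wild_type),
        target_curve=curve(gene_id),
        reference_curve=curve(reference))


def transcript_accounting(shares: tuple[float, float],
                          fold_changes: tuple[float, float],
                          ) -> TranscriptShare:
    """Percent-of-wild-type transcript totals from shares and fold-changes.

    With wild-type shares (pA, pB) summing to 100 and linear fold-changes
    (fA, fB), the mutant pool is pA*fA + pB*fB percent of wild-type.
    """
    pa, pb = shares
    fa, fb = fold_changes
    if pa < 0 or pb < 0 or abs(pa + pb - 100.0) > 1e-9:
        raise ValueError("shares must be non-negative and sum to 100")
    if fa < 0 or fb < 0:
        raise ValueError("fold-changes must be non-negative")
    return TranscriptShare(pa, pb, fa, fb)
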