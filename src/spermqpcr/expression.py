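"""Quantification mathematics for RT-qPCR expression analysis.

Covers the chain from raw Cq values to comparable expression numbers:

* amplification-efficiency calibration from a dilution series
  (``E = (10^(-1/slope) - 1) * 100`` with Cq regressed on log10 input),
* melt-curve quality control (Tm from the −dF/dT peak, exclusion of
  shifted-Tm or low-peak products),
* genomic-DNA correction of exon Cq values using a matched intron
  amplicon: ``Cq_mRNA = −log2(2^−Cq_exon − 2^−Cq_intron)``,
* relative expression by the ΔΔCq method against a reference gene and a
  calibrator sample, and
* dispersion metrics (CV% and quartile deviation) used to judge assay
  consistency.

Censoring is a value, not an exception: a sample whose exon signal does not
exceed its intron (gDNA) signal has no measurable mRNA and is carried
through as censored with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .qpcr_data import CqDataset, FormatError

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# amplification efficiency

@dataclass(frozen=True)
class DilutionSeries:
    """Calibration points (template amount in ng, observed Cq) for one gene."""

    gene: str
    points: tuple  # of (amount_ng, cq)

    def __post_init__(self):
        amounts = [a for a, _ in self.points]
        if any(a <= 0 for a in amounts):
            raise ValueError("all template amounts must be positive")
        object.__setattr__(self, "points", tuple((float(a), float(c)) for a, c in self.points))

    @property
    def n_distinct_amounts(self) -> int:
        return len({a for a, _ in self.points})


@dataclass(frozen=True)
class EfficiencyResult:
    gene: str
    slope: float  # cycles per log10(amount)
    intercept: float
    r_squared: float
    efficiency_percent: float | None  # None when the fit is invalid
    valid: bool


def fit_efficiency(series: DilutionSeries) -> EfficiencyResult:
    """Ordinary least squares of Cq on log10(template amount).

    A valid assay has a negative slope; 100% efficiency corresponds to
    −1/log10(2) ≈ −3.3219 cycles per decade.  A non-negative slope is
    flagged invalid and no efficiency is reported.
    """
    if series.n_distinct_amounts < 3:
        raise ValueError("dilution series needs >= 3 distinct amounts")
    amounts = np.array([a for a, _ in series.points])
    cqs = np.array([c for _, c in series.points])
    fit = stats.linregress(np.log10(amounts), cqs)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue**2)
    if slope >= 0:
        return EfficiencyResult(series.gene, slope, intercept, r2, None, False)
    eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return EfficiencyResult(series.gene, slope, intercept, r2, float(eff), True)


# ---------------------------------------------------------------------------
# melt-curve QC

@dataclass(frozen=True)
class MeltCurve:
    sample_id: str
    gene: str
    temperature: tuple  # degrees C, strictly increasing
    fluorescence: tuple

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.size != f.size:
            raise FormatError("temperature and fluorescence lengths differ")
        if t.size < 10 or t[-1] - t[0] < 10:
            raise FormatError("melt curve needs >= 10 points spanning >= 10 degC")
        if np.any(np.diff(t) <= 0):
            raise FormatError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperature", tuple(t))
        object.__setattr__(self, "fluorescence", tuple(f))


@dataclass(frozen=True)
class MeltQcResult:
    sample_id: str
    gene: str
    tm: float
    peak_height: float
    excluded: bool
    reason: str  # "none" | "tm_shift" | "low_peak"


def _melt_peak(curve: MeltCurve, smooth: bool = True) -> tuple[float, float]:
    t = np.asarray(curve.temperature)
    f = np.asarray(curve.fluorescence)
    d = -np.gradient(f, t)  # central differences inside, one-sided at ends
    if smooth and d.size >= 3:
        d = np.convolve(d, np.ones(3) / 3.0, mode="same")
    i = int(np.argmax(d))
    return float(t[i]), float(d[i])


def melt_qc(
    curves: Sequence[MeltCurve],
    tm_tolerance: float = 1.5,
    peak_fraction: float = 0.5,
    smooth: bool = True,
) -> list[MeltQcResult]:
    """Flag melt curves whose product differs from the rest of their gene group.

    Tm is the temperature of the −dF/dT maximum (3-point boxcar smoothing by
    default).  Within each gene group a curve is excluded with reason
    ``tm_shift`` when its Tm deviates from the group median by more than
    ``tm_tolerance`` °C, or with ``low_peak`` when its peak height falls
    below ``peak_fraction`` of the group median peak height.
    """
    by_gene: dict[str, list[MeltCurve]] = {}
    for c in curves:
        by_gene.setdefault(c.gene, []).append(c)
    results = []
    for gene, group in by_gene.items():
        if len(group) < 2:
            raise ValueError(f"gene {gene!r}: need >= 2 curves for a group median")
        peaks = [_melt_peak(c, smooth=smooth) for c in group]
        med_tm = float(np.median([tm for tm, _ in peaks]))
        med_h = float(np.median([h for _, h in peaks]))
        for c, (tm, h) in zip(group, peaks):
            if abs(tm - med_tm) > tm_tolerance:
                results.append(MeltQcResult(c.sample_id, gene, tm, h, True, "tm_shift"))
            elif h < peak_fraction * med_h:
                results.append(MeltQcResult(c.sample_id, gene, tm, h, True, "low_peak"))
            else:
                results.append(MeltQcResult(c.sample_id, gene, tm, h, False, "none"))
    return results


# ---------------------------------------------------------------------------
# genomic-DNA correction

def gdna_corrected_cq(cq_exon: float, cq_intron: float) -> float | None:
    """Remove the genomic-DNA component from an exon Cq.

    The exon amplicon sees mRNA plus gDNA; the intron amplicon sees gDNA
    only.  Subtracting in the linear quantity domain and re-expressing as a
    cycle number gives ``−log2(2^−Cq_exon − 2^−Cq_intron)``, evaluated here
    in the numerically stable form ``Cq_exon − log2(1 − 2^(Cq_exon −
    Cq_intron))``.  When the exon signal does not exceed the intron signal
    (``cq_exon >= cq_intron``) there is no measurable mRNA and the result is
    censored (None).
    """
    if cq_exon >= cq_intron:
        return None
    return float(cq_exon - np.log1p(-np.exp2(cq_exon - cq_intron)) / _LN2)


@dataclass(frozen=True)
class CorrectedExpression:
    sample_id: str
    gene: str
    cq_exon: float | None
    cq_intron: float | None
    cq_mrna: float | None
    relative_expression: float | None
    censored_reason: str = ""  # "" | "gdna_dominated" | "missing_reference" | ...


# ---------------------------------------------------------------------------
# relative expression (ddCq)

def relative_expression_ddcq(
    ds: CqDataset,
    target: str,
    reference: str,
    calibrator: str,
    use_gdna_correction: bool = False,
) -> list[CorrectedExpression]:
    """Relative expression of ``target`` by the ΔΔCq method.

    ΔCq_s = Cq_target,s − Cq_reference,s and the fold change is
    2^−(ΔCq_s − ΔCq_calibrator), so the calibrator sample is exactly 1.
    With ``use_gdna_correction`` the target's exon Cq is first corrected
    with its matched intron Cq; the reference gene is never corrected.
    Expects one measurement per (sample, gene, primer class) — aggregate
    replicates first.  Samples with a missing reference or a gDNA-dominated
    corrected Cq propagate as censored with a reason.
    """
    exon: dict[str, float | None] = {}
    intron: dict[str, float | None] = {}
    ref: dict[str, float | None] = {}
    for m in ds:
        if m.gene == target and m.primer_class == "exon":
            exon[m.sample_id] = m.cq
        elif m.gene == target and m.primer_class == "intron":
            intron[m.sample_id] = m.cq
        elif m.gene == reference and m.primer_class == "exon":
            ref[m.sample_id] = m.cq

    def corrected(sample: str) -> tuple[float | None, str]:
        e = exon.get(sample)
        if e is None:
            return None, "censored_target"
        if not use_gdna_correction:
            return e, ""
        i = intron.get(sample)
        if i is None:
            return None, "missing_intron"
        c = gdna_corrected_cq(e, i)
        if c is None:
            return None, "gdna_dominated"
        return c, ""

    cal_cq, cal_reason = corrected(calibrator)
    cal_ref = ref.get(calibrator)
    if cal_cq is None or cal_ref is None:
        raise ValueError(
            f"calibrator {calibrator!r} has no usable target/reference Cq"
            + (f" ({cal_reason})" if cal_reason else "")
        )
    dcq_cal = cal_cq - cal_ref

    out = []
    for sample in sorted(exon):
        cq_mrna, reason = corrected(sample)
        r = ref.get(sample)
        rel = None
        if cq_mrna is not None and r is None:
            reason = "missing_reference"
        elif cq_mrna is not None:
            rel = float(2.0 ** (-((cq_mrna - r) - dcq_cal)))
        out.append(
            CorrectedExpression(
                sample_id=sample,
                gene=target,
                cq_exon=exon.get(sample),
                cq_intron=intron.get(sample),
                cq_mrna=cq_mrna,
                relative_expression=rel,
                censored_reason=reason,
            )
        )
    return out


# ---------------------------------------------------------------------------
# dispersion

@dataclass(frozen=True)
class DispersionMetrics:
    cv_percent: float | None  # undefined when the mean is <= 0
    quartile_deviation: float


def dispersion(values: Iterable[float]) -> DispersionMetrics:
    """CV% (sample SD over mean) and quartile deviation (Q3−Q1)/2.

    Quartiles use linear interpolation between order statistics.  Requires
    at least 4 numeric values; a non-positive mean leaves the CV undefined.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 4:
        raise ValueError("dispersion needs >= 4 values")
    q1, q3 = np.percentile(x, [25, 75])
    qd = float((q3 - q1) / 2.0)
    mean = x.mean()
    if mean <= 0:
        return DispersionMetrics(None, qd)
    cv = float(100.0 * x.std(ddof=1) / mean)
    return DispersionMetrics(cv, qd)
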