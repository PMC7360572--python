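"""Seeded generator of complete synthetic sperm-RNA qPCR studies.

Emulates the structure of a 20-boar fertility cohort: per-boar mean litter
sizes, marker transcript abundances correlated with litter size at a
configurable signed r, a per-sample genomic-DNA (gDNA) contamination load
that drives the intron amplicon, matched exon/intron Cq tables across DNase
treatment arms with technical-replicate noise, RNA-yield/purity QC records,
5-point dilution series for efficiency calibration, and sigmoidal melt
curves with optional shifted-Tm outliers.

The generative model, in Cq space (log2 quantity, inverted):

* litter_i ~ Normal(litter_mean, litter_sd)
* standardized marker abundance z_{m,i} = r_m z(litter_i) + sqrt(1-r_m^2) eps
* true mRNA Cq = baseline_cq_m − scale · z_{m,i}
* intron Cq = baseline_cq_m + gdna_log2_offset + g_i (gDNA only)
* exon Cq = −log2(2^−Cq_mRNA + 2^−Cq_intron)  (mRNA plus gDNA)

so the analytical gDNA correction inverts the exon/intron mixture exactly up
to replicate noise.  The DNase arm multiplies RNA yield by
``dnase_yield_factor``, severs the abundance–litter correlation when
``dnase_kills_correlation`` is set, and adds ``dnase_mrna_log2_penalty``
cycles to the mRNA component, narrowing the exon−intron gap the way
degraded RNA does.

Randomness is split deterministically per boar/gene/stream (a CRC of the
gene name keys its stream), so adding a marker to the config does not
perturb draws already made for existing markers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .expression import DilutionSeries, MeltCurve
from .fertility import FertilityRecord
from .qpcr_data import CqDataset, CqMeasurement, RnaQcRecord


@dataclass(frozen=True)
class MarkerSpec:
    name: str
    target_r: float  # signed marker-abundance vs litter-size correlation
    baseline_cq: float

    def __post_init__(self):
        if not abs(self.target_r) < 1:
            raise ValueError("|target_r| must be < 1")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """All generative parameters of a simulated cohort study.

    Defaults reproduce the study conditions the analysis targets: 20 boars,
    litter sizes around 12.67 with SD 0.65 (the cohort SE of 0.14 scaled by
    sqrt(20)), one marker negatively correlated with fertility at r = −0.34
    and one positively at +0.32, triplicate wells with 0.2-cycle noise, and
    a DNase arm that keeps only 44% of the RNA yield and destroys the
    abundance–fertility correlation.
    """

    n_boars: int = 20
    n_replicates: int = 3
    litter_mean: float = 12.67
    litter_sd: float = 0.65
    markers: tuple = (
        MarkerSpec("EQTN", -0.34, 26.0),
        MarkerSpec("PRDX4", +0.32, 27.0),
    )
    reference_gene: str = "GAPDH"
    reference_baseline_cq: float = 22.0
    abundance_scale_log2: float = 1.0  # cycles per SD of marker abundance
    gdna_log2_offset: float = 5.0  # intron Cq above the marker baseline
    gdna_contamination_sd: float = 1.0  # cycles, per-sample gDNA load spread
    cq_noise_sd: float = 0.2  # technical replicate noise, cycles
    reference_biological_sd: float = 0.3  # per-sample reference-gene spread
    dnase_yield_factor: float = 0.44  # treated/untreated concentration ratio
    dnase_yield_jitter_sd: float = 0.25  # lognormal, mean-one
    dnase_kills_correlation: bool = True
    dnase_mrna_log2_penalty: float = 6.0  # cycles of mRNA signal lost to DNase
    # RNA yield distribution, lognormal derived from the reference cohort's
    # untreated mean 101.7 ng/uL and SD ~60 ng/uL
    concentration_log_mean: float = 4.473
    concentration_log_sd: float = 0.546
    purity_mean: float = 1.80
    purity_sd: float = 0.08
    plate_offset_cycles: float = 0.0  # constant Cq shift, ddCq-invariant
    max_cycles: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.n_boars < 2 or self.n_replicates < 1:
            raise ValueError("need n_boars >= 2 and n_replicates >= 1")
        if not 0 < self.dnase_yield_factor <= 1:
            raise ValueError("dnase_yield_factor must be in (0, 1]")
        for sd in (self.litter_sd, self.gdna_contamination_sd, self.cq_noise_sd,
                   self.purity_sd, self.dnase_yield_jitter_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        markers = tuple(
            m if isinstance(m, MarkerSpec) else MarkerSpec(*m) for m in self.markers
        )
        object.__setattr__(self, "markers", markers)


@dataclass
class SyntheticTruth:
    """Latent state behind a simulated cohort, for parameter-recovery checks."""

    litter_size: np.ndarray  # per boar
    abundance_z: dict  # gene -> arm -> per-boar standardized abundance
    gdna_load: np.ndarray  # cycles, per boar
    realized_r: dict  # gene -> arm -> sample Pearson r(abundance, litter)
    config: SyntheticCohortConfig


_ARMS = ("untreated", "treated")


def _stream(seed: int, *keys) -> np.random.Generator:
    """Independent child generator for a named simulation stream."""
    ints = [seed]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def simulate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[CqDataset, list[RnaQcRecord], list[FertilityRecord], SyntheticTruth]:
    """Draw one complete cohort under ``config`` (pure function of config+seed)."""
    cfg = config
    n = cfg.n_boars
    seed = cfg.seed
    boars = [f"boar{i + 1:03d}" for i in range(n)]

    litter = _stream(seed, "litter").normal(cfg.litter_mean, cfg.litter_sd, n)
    litter = np.clip(litter, 1.0, None)
    z_lit = (litter - cfg.litter_mean) / cfg.litter_sd if cfg.litter_sd > 0 else np.zeros(n)
    gdna = _stream(seed, "gdna").normal(0.0, cfg.gdna_contamination_sd, n)

    fixed_tags = {"storage": "-80C", "stabilizer": "snap_frozen", "rt_primer": "oligo_dt"}
    measurements: list[CqMeasurement] = []
    abundance_z: dict = {}
    realized_r: dict = {}

    def add_measurement(boar, gene, primer, arm, rep, cq):
        cq = float(cq) + cfg.plate_offset_cycles
        if cq > cfg.max_cycles:  # beyond the cycle ceiling: undetermined well
            cq = None
        cond = dict(fixed_tags, dnase=arm)
        measurements.append(
            CqMeasurement(boar, gene, primer, cond, rep, cq)
        )

    for m in cfg.markers:
        eps = _stream(seed, "marker_eps", m.name).standard_normal(n)
        z_u = m.target_r * z_lit + np.sqrt(1 - m.target_r**2) * eps
        if cfg.dnase_kills_correlation:
            z_t = _stream(seed, "marker_eps_dnase", m.name).standard_normal(n)
        else:
            z_t = z_u
        abundance_z[m.name] = {"untreated": z_u, "treated": z_t}
        realized_r[m.name] = {
            "untreated": _pearson(z_u, litter),
            "treated": _pearson(z_t, litter),
        }
        cq_intron_true = m.baseline_cq + cfg.gdna_log2_offset + gdna
        for arm, z in (("untreated", z_u), ("treated", z_t)):
            cq_mrna = m.baseline_cq - cfg.abundance_scale_log2 * z
            if arm == "treated":
                cq_mrna = cq_mrna + cfg.dnase_mrna_log2_penalty
            cq_exon_true = -np.log2(np.exp2(-cq_mrna) + np.exp2(-cq_intron_true))
            noise = _stream(seed, "cq_noise", m.name, arm)
            for i, boar in enumerate(boars):
                for rep in range(1, cfg.n_replicates + 1):
                    add_measurement(
                        boar, m.name, "exon", arm, rep,
                        cq_exon_true[i] + noise.normal(0, cfg.cq_noise_sd),
                    )
                    add_measurement(
                        boar, m.name, "intron", arm, rep,
                        cq_intron_true[i] + noise.normal(0, cfg.cq_noise_sd),
                    )

    # reference gene: exon amplicon only, uncorrelated with litter size
    for arm in _ARMS:
        bio = _stream(seed, "ref_bio", cfg.reference_gene, arm)
        noise = _stream(seed, "cq_noise", cfg.reference_gene, arm)
        ref_true = cfg.reference_baseline_cq + bio.normal(
            0, cfg.reference_biological_sd, n
        )
        for i, boar in enumerate(boars):
            for rep in range(1, cfg.n_replicates + 1):
                add_measurement(
                    boar, cfg.reference_gene, "exon", arm, rep,
                    ref_true[i] + noise.normal(0, cfg.cq_noise_sd),
                )

    # RNA QC records: yield lognormal, DNase arm scaled by the yield factor
    conc_rng = _stream(seed, "concentration")
    conc_u = np.exp(conc_rng.normal(cfg.concentration_log_mean,
                                    cfg.concentration_log_sd, n))
    jit_sd = cfg.dnase_yield_jitter_sd
    jitter = np.exp(_stream(seed, "yield_jitter").normal(-jit_sd**2 / 2, jit_sd, n))
    conc_t = conc_u * cfg.dnase_yield_factor * jitter
    purity_rng = _stream(seed, "purity")
    ratio_u = np.clip(purity_rng.normal(cfg.purity_mean, cfg.purity_sd, n), 1.0, None)
    ratio_t = np.clip(purity_rng.normal(cfg.purity_mean, cfg.purity_sd, n), 1.0, None)

    qc = []
    for i, boar in enumerate(boars):
        qc.append(RnaQcRecord(boar, float(conc_u[i]), float(ratio_u[i]),
                              "untreated", float(litter[i])))
        qc.append(RnaQcRecord(boar, float(conc_t[i]), float(ratio_t[i]),
                              "treated", float(litter[i])))

    trials = _stream(seed, "ai_trials").normal(17.25, 1.98, n)
    fert = [
        FertilityRecord(boar, float(litter[i]), int(max(1, round(trials[i]))))
        for i, boar in enumerate(boars)
    ]

    truth = SyntheticTruth(
        litter_size=litter,
        abundance_z=abundance_z,
        gdna_load=gdna,
        realized_r=realized_r,
        config=cfg,
    )
    return CqDataset(measurements, max_cycles=cfg.max_cycles), qc, fert, truth


# ---------------------------------------------------------------------------

DEFAULT_DILUTION_AMOUNTS = (250.0, 100.0, 50.0, 25.0, 10.0)


def simulate_dilution_series(
    gene: str,
    true_efficiency_percent: float,
    amounts=DEFAULT_DILUTION_AMOUNTS,
    noise_sd: float = 0.0,
    seed: int = 0,
    cq_at_100ng: float = 25.0,
    replicates: int = 1,
) -> DilutionSeries:
    """Calibration-curve data from the exact efficiency model plus noise.

    An assay with per-cycle amplification factor (1 + E/100) has
    Cq = const − log_{1+E/100}(amount), i.e. slope −1/log10(1 + E/100)
    cycles per decade of template.
    """
    if not 50 < true_efficiency_percent <= 120:
        raise ValueError("efficiency must lie in (50, 120] percent")
    if any(a <= 0 for a in amounts):
        raise ValueError("amounts must be positive")
    slope = -1.0 / np.log10(1.0 + true_efficiency_percent / 100.0)
    rng = np.random.default_rng([seed, zlib.crc32(gene.encode()) & 0x7FFFFFFF])
    points = []
    for a in amounts:
        for _ in range(replicates):
            cq = cq_at_100ng + slope * (np.log10(a) - 2.0)
            if noise_sd > 0:
                cq += rng.normal(0, noise_sd)
            points.append((a, float(cq)))
    return DilutionSeries(gene=gene, points=tuple(points))


def simulate_melt_curves(
    n: int,
    tm: float = 84.0,
    outlier_fraction: float = 0.0,
    tm_shift: float = 3.0,
    seed: int = 0,
    gene: str = "GAPDH",
    temp_range: tuple = (65.0, 95.0),
    temp_step: float = 0.5,
) -> list[MeltCurve]:
    """Sigmoidal dissociation curves whose −dF/dT peaks at ``tm`` (±0.3 °C
    jitter).  A fraction of curves are outliers: Tm displaced by
    ``tm_shift`` °C and amplitude attenuated to 30%, the signature of an
    off-target product."""
    if not 0 <= outlier_fraction < 0.5:
        raise ValueError("outlier_fraction must lie in [0, 0.5)")
    rng = np.random.default_rng([seed, zlib.crc32(gene.encode()) & 0x7FFFFFFF])
    temps = np.arange(temp_range[0], temp_range[1] + temp_step / 2, temp_step)
    n_out = int(round(outlier_fraction * n))
    outlier_idx = set(rng.choice(n, size=n_out, replace=False).tolist()) if n_out else set()
    curves = []
    for j in range(n):
        tm_j = tm + rng.uniform(-0.3, 0.3)
        amp = 1000.0 * rng.uniform(0.9, 1.1)
        if j in outlier_idx:
            tm_j += tm_shift
            amp *= 0.3
        width = 0.8
        fluor = amp / (1.0 + np.exp((temps - tm_j) / width)) + 50.0
        curves.append(
            MeltCurve(
                sample_id=f"well{j + 1:02d}",
                gene=gene,
                temperature=tuple(temps),
                fluorescence=tuple(fluor),
            )
        )
    return curves
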