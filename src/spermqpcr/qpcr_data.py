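"""Domain types and delimited-file I/O for qPCR Cq experiments.

The central container is :class:`CqDataset`, a collection of per-well
quantification-cycle (Cq) measurements keyed by sample, gene, primer class
(exon / intron / exon-exon junction) and an open set of treatment-condition
tags (storage temperature, stabilizer, DNase arm, RT primer, control role).
Wells the instrument reports as "Undetermined" are kept as *censored*
measurements rather than being coerced to the cycle ceiling, so that
downstream means are not silently biased.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PRIMER_CLASSES = ("exon", "intron", "junction")

#: condition columns recognised in the flat CSV interface
CONDITION_COLUMNS = ("storage", "stabilizer", "dnase", "rt_primer", "control")

DEFAULT_MAX_CYCLES = 40.0


class FormatError(ValueError):
    """A delimited input file violates the expected layout."""


class IntegrityError(ValueError):
    """Parsed content violates a dataset invariant (duplicate keys, bad values)."""


@dataclass(frozen=True)
class CqMeasurement:
    """One well: a Cq value (or censored-at-max) for a sample/gene/primer."""

    sample_id: str
    gene: str
    primer_class: str
    condition: Mapping[str, str] = field(default_factory=dict)
    replicate: int = 1
    cq: float | None = None
    censored_count: int = 0

    def __post_init__(self):
        if self.primer_class not in PRIMER_CLASSES:
            raise FormatError(
                f"unknown primer_class {self.primer_class!r}; "
                f"expected one of {PRIMER_CLASSES}"
            )
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        object.__setattr__(self, "condition", dict(self.condition))

    @property
    def censored(self) -> bool:
        return self.cq is None

    def key(self) -> tuple:
        cond = tuple(sorted(self.condition.items()))
        return (self.sample_id, self.gene, self.primer_class, cond, self.replicate)


@dataclass
class CqDataset:
    """A set of Cq measurements with unique (sample, gene, primer, condition,
    replicate) keys and a shared cycle ceiling."""

    measurements: list[CqMeasurement]
    max_cycles: float = DEFAULT_MAX_CYCLES

    def __post_init__(self):
        seen = set()
        for m in self.measurements:
            if m.cq is not None and not (0 < m.cq <= self.max_cycles):
                raise IntegrityError(
                    f"cq {m.cq} outside (0, {self.max_cycles}] for {m.key()}"
                )
            k = m.key()
            if k in seen:
                raise IntegrityError(f"duplicate measurement key {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def subset(self, **tags: str) -> "CqDataset":
        """Measurements whose condition tags match every given key=value."""
        keep = [
            m
            for m in self.measurements
            if all(m.condition.get(k) == v for k, v in tags.items())
        ]
        return CqDataset(keep, max_cycles=self.max_cycles)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.measurements:
            row = {
                "sample_id": m.sample_id,
                "gene": m.gene,
                "primer_class": m.primer_class,
                "replicate": m.replicate,
                "cq": m.cq,
                "censored_count": m.censored_count,
            }
            row.update(m.condition)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RnaQcRecord:
    """Per-sample RNA yield and spectrophotometric purity for one DNase arm."""

    sample_id: str
    concentration: float  # ng/uL
    purity_260_280: float
    dnase: str  # "treated" | "untreated"
    litter_size: float | None = None
    litter_size_se: float | None = None

    def __post_init__(self):
        if self.concentration <= 0:
            raise IntegrityError(
                f"non-positive concentration for {self.sample_id}"
            )
        if self.purity_260_280 <= 0:
            raise IntegrityError(f"non-positive 260/280 ratio for {self.sample_id}")


@dataclass(frozen=True)
class ControlReport:
    """Outcome of the no-RT / no-template control check for one gene.

    ``delta_cq_no_rt`` is Cq(no reverse transcriptase) − Cq(template): the
    cycle gap attributable to residual genomic DNA.  A large gap means the
    template signal is dominated by cDNA, not gDNA carry-over.
    """

    gene: str
    delta_cq_no_rt: float | None
    ntc_amplified: bool
    passed: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# delimited I/O

_REQUIRED_CQ_COLUMNS = ("sample_id", "gene", "primer_class", "replicate", "cq")


def _sniff_sep(path: Path) -> str:
    header = Path(path).open().readline()
    return "\t" if "\t" in header else ","


def read_cq_table(path, max_cycles: float = DEFAULT_MAX_CYCLES) -> CqDataset:
    """Read a long-format Cq table (CSV or TSV, auto-detected).

    Required columns: sample_id, gene, primer_class, replicate, cq.  Any
    further columns are stored as condition tags.  A cq of ``Undetermined``
    (case-insensitive) or an empty cell is a censored measurement.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_CQ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    tag_cols = [c for c in df.columns if c not in _REQUIRED_CQ_COLUMNS
                and c != "censored_count"]
    measurements = []
    for row in df.itertuples(index=False):
        raw = getattr(row, "cq").strip()
        if raw == "" or raw.lower() == "undetermined":
            cq = None
        else:
            cq = float(raw)
        cond = {c: getattr(row, c) for c in tag_cols if getattr(row, c) != ""}
        ccount = int(getattr(row, "censored_count", 0) or 0)
        measurements.append(
            CqMeasurement(
                sample_id=row.sample_id,
                gene=row.gene,
                primer_class=row.primer_class,
                condition=cond,
                replicate=int(row.replicate),
                cq=cq,
                censored_count=ccount,
            )
        )
    return CqDataset(measurements, max_cycles=max_cycles)


def write_cq_table(ds: CqDataset, path, sep: str = ",") -> None:
    """Write a dataset in the flat dialect read_cq_table accepts (round-trips)."""
    tag_cols = sorted({k for m in ds for k in m.condition})
    cols = list(_REQUIRED_CQ_COLUMNS) + ["censored_count"] + tag_cols
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(cols)
        for m in ds:
            w.writerow(
                [
                    m.sample_id,
                    m.gene,
                    m.primer_class,
                    m.replicate,
                    "" if m.cq is None else repr(float(m.cq)),
                    m.censored_count,
                ]
                + [m.condition.get(c, "") for c in tag_cols]
            )


def read_rna_qc_table(path) -> list[RnaQcRecord]:
    """Read an RNA-QC table: sample_id, litter_size, concentration_ng_ul,
    ratio_260_280, dnase (CSV or TSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    required = ("sample_id", "concentration_ng_ul", "ratio_260_280", "dnase")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        ls = getattr(row, "litter_size", None)
        se = getattr(row, "litter_size_se", None)
        records.append(
            RnaQcRecord(
                sample_id=str(row.sample_id),
                concentration=float(row.concentration_ng_ul),
                purity_260_280=float(row.ratio_260_280),
                dnase=str(row.dnase),
                litter_size=None if ls is None or pd.isna(ls) else float(ls),
                litter_size_se=None if se is None or pd.isna(se) else float(se),
            )
        )
    return records


def write_rna_qc_table(records: Sequence[RnaQcRecord], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["sample_id", "litter_size", "litter_size_se",
             "concentration_ng_ul", "ratio_260_280", "dnase"]
        )
        for r in records:
            w.writerow(
                [
                    r.sample_id,
                    "" if r.litter_size is None else r.litter_size,
                    "" if r.litter_size_se is None else r.litter_size_se,
                    r.concentration,
                    r.purity_260_280,
                    r.dnase,
                ]
            )


def load_table1() -> list[RnaQcRecord]:
    """The packaged 20-boar RNA-QC reference table (both DNase arms)."""
    ref = resources.files("spermqpcr.data").joinpath("table1.csv")
    with resources.as_file(ref) as p:
        return read_rna_qc_table(p)


# ---------------------------------------------------------------------------
# replicate aggregation

def aggregate_replicates(ds: CqDataset, policy: str = "mean") -> CqDataset:
    """Collapse technical replicates to one Cq per (sample, gene, primer,
    condition).

    Numeric replicates are combined by ``policy`` (mean or median).  A group
    that is entirely censored stays censored; a mixed group combines the
    numeric replicates only and records how many wells were censored.
    """
    if len(ds) == 0:
        raise ValueError("cannot aggregate an empty dataset")
    if policy not in ("mean", "median"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    agg = np.mean if policy == "mean" else np.median
    groups: dict[tuple, list[CqMeasurement]] = {}
    for m in ds:
        k = m.key()[:-1]  # drop replicate
        groups.setdefault(k, []).append(m)
    out = []
    for (sample, gene, primer, cond), ms in groups.items():
        vals = [m.cq for m in ms if m.cq is not None]
        n_cens = sum(1 for m in ms if m.cq is None) + sum(m.censored_count for m in ms)
        out.append(
            CqMeasurement(
                sample_id=sample,
                gene=gene,
                primer_class=primer,
                condition=dict(cond),
                replicate=1,
                cq=float(agg(vals)) if vals else None,
                censored_count=n_cens,
            )
        )
    return CqDataset(out, max_cycles=ds.max_cycles)


# ---------------------------------------------------------------------------
# negative-control validation

def validate_controls(
    ds: CqDataset, no_rt_threshold: float = 3.0
) -> list[ControlReport]:
    """Check no-RT and no-template controls gene by gene.

    Control wells carry a ``control`` condition tag: ``template`` (or no tag),
    ``no_rt``, or ``ntc``.  The check passes iff Cq(no-RT) − Cq(template) is
    at least ``no_rt_threshold`` cycles and no NTC well amplified.  A censored
    no-RT well is substituted with ``max_cycles`` (a conservative lower bound
    on the true difference); a missing no-RT series fails with a reason rather
    than raising.
    """
    genes = sorted({m.gene for m in ds})
    reports = []
    for gene in genes:
        ms = [m for m in ds if m.gene == gene]
        template = [
            m.cq for m in ms
            if m.condition.get("control", "template") == "template"
            and m.cq is not None
        ]
        no_rt = [m for m in ms if m.condition.get("control") == "no_rt"]
        ntc = [m for m in ms if m.condition.get("control") == "ntc"]
        ntc_amp = any(m.cq is not None for m in ntc)
        if not no_rt:
            reports.append(
                ControlReport(gene, None, ntc_amp, False, "no no-RT series")
            )
            continue
        if not template:
            reports.append(
                ControlReport(gene, None, ntc_amp, False, "no template series")
            )
            continue
        no_rt_vals = [ds.max_cycles if m.cq is None else m.cq for m in no_rt]
        delta = float(np.mean(no_rt_vals) - np.mean(template))
        passed = delta >= no_rt_threshold and not ntc_amp
        reason = ""
        if delta < no_rt_threshold:
            reason = f"no-RT delta {delta:.2f} below threshold {no_rt_threshold}"
        elif ntc_amp:
            reason = "no-template control amplified"
        reports.append(ControlReport(gene, delta, ntc_amp, passed, reason))
    return reports
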