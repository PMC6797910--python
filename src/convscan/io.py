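"""Standard-format I/O and shared domain types.

Covers gapped protein FASTA alignments (via Biopython), per-taxon trait
tables (TSV), the per-site report table, and the analysis configuration.
Tree I/O lives in :mod:`convscan.tree`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AA_ORDER",
    "AA_INDEX",
    "GAP",
    "Alignment",
    "TraitTable",
    "AnalysisConfig",
    "SiteRow",
    "SiteReport",
    "read_alignment",
    "write_alignment",
    "read_trait_table",
    "write_site_report",
    "read_site_report",
]

#: Fixed residue order used throughout (profiles, encodings, simulators).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
#: Integer code for a gap (or masked) position.
GAP = -1
# Ambiguity/placeholder characters coerced to gap: translated transcriptome
# data must not inject states outside the 20-letter model alphabet.
_GAP_CHARS = {"-", "X", "?", "."}

CALL_VALUES = ("adaptive", "non_adaptive", "unresolved", "below_threshold", "skipped_gaps")


@dataclass
class Alignment:
    """A taxa x sites protein alignment, residues encoded 0..19, gaps -1."""

    taxa: list[str]
    data: np.ndarray  # shape (n_taxa, n_sites), dtype int8

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in alignment")
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("alignment matrix shape does not match taxa")

    @property
    def length(self) -> int:
        return self.data.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def column(self, site_index: int) -> dict[str, int]:
        """Column as taxon -> residue code (1-based site index)."""
        col = self.data[:, site_index - 1]
        return dict(zip(self.taxa, (int(c) for c in col)))

    def sequence(self, taxon: str) -> str:
        row = self.data[self.taxa.index(taxon)]
        return "".join("-" if c == GAP else AA_ORDER[c] for c in row)


def encode_sequence(seq: str, taxon: str = "?") -> np.ndarray:
    codes = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        if ch in _GAP_CHARS:
            codes[i] = GAP
        else:
            try:
                codes[i] = AA_INDEX[ch]
            except KeyError:
                raise ValueError(
                    f"invalid residue {ch!r} at position {i + 1} in {taxon}"
                ) from None
    return codes


def read_alignment(path: str | Path) -> Alignment:
    """Read a gapped protein FASTA alignment.

    'X', '?' and '.' are normalised to '-'.  Ragged records raise an error
    naming the offending taxon.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    taxa: list[str] = []
    rows: list[np.ndarray] = []
    length = None
    for rec in records:
        seq = str(rec.seq)
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"ragged alignment: {rec.id} has length {len(seq)}, expected {length}"
            )
        taxa.append(rec.id)
        rows.append(encode_sequence(seq, rec.id))
    return Alignment(taxa, np.vstack(rows))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(aln.sequence(t)), id=t, description="") for t in aln.taxa
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Trait tables


@dataclass
class TraitTable:
    """Taxon -> continuous trait value (degC, or log10 m after transform)."""

    entries: dict[str, float]

    def __post_init__(self):
        for taxon, value in self.entries.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite trait value for {taxon}")

    def __getitem__(self, taxon: str) -> float:
        return self.entries[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.entries

    def taxa(self) -> list[str]:
        return list(self.entries)


def read_trait_table(path: str | Path, transform: str = "none") -> TraitTable:
    """Read a two-column trait TSV (header ``taxon<TAB>value``; '#' comments).

    ``transform="log10_depth"`` maps depth in meters to log10(m); depths must
    be strictly positive.
    """
    if transform not in ("none", "log10_depth"):
        raise ValueError(f"unknown transform {transform!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if list(df.columns[:2]) != ["taxon", "value"]:
        raise ValueError(
            f"trait table must have header 'taxon\\tvalue', got {list(df.columns)}"
        )
    entries: dict[str, float] = {}
    for taxon, raw in zip(df["taxon"], df["value"]):
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric trait value {raw!r} for {taxon}") from None
        if not math.isfinite(value):
            raise ValueError(f"non-finite trait value for {taxon}")
        if taxon in entries:
            raise ValueError(f"duplicate taxon {taxon!r} in trait table")
        if transform == "log10_depth":
            if value <= 0:
                raise ValueError(f"nonpositive depth {value} for {taxon}")
            value = math.log10(value)
        entries[taxon] = value
    return TraitTable(entries)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class AnalysisConfig:
    """Knobs of the whole pipeline, with the defaults used in the analysis.

    bin_width: trait bin width (1.75 for degC, 0.2 for log10 m).
    min_transitions: minimum independent transition events per scenario.
    pp_threshold: PP below which a site is not bootstrapped.
    n_sims: simulations per bootstrap arm.
    confidence: bootstrap confidence level (alpha = beta = 1 - confidence).
    noise_concentration: Dirichlet concentration of null-arm profile noise.
    branch_noise_sigma: lognormal sigma of optional branch-length noise (off at 0).
    seed: base RNG seed; per-site streams are derived from it.
    """

    bin_width: float = 1.75
    min_transitions: int = 5
    pp_threshold: float = 0.5
    n_sims: int = 1000
    confidence: float = 0.95
    noise_concentration: float = 100.0
    branch_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.bin_width > 0:
            raise ValueError("bin_width must be > 0")
        if self.min_transitions < 1:
            raise ValueError("min_transitions must be >= 1")
        if not 0 < self.pp_threshold < 1:
            raise ValueError("pp_threshold must be in (0, 1)")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not 0.5 < self.confidence < 1:
            raise ValueError("confidence must be in (0.5, 1)")
        if not self.noise_concentration > 0:
            raise ValueError("noise_concentration must be > 0")
        if self.branch_noise_sigma < 0:
            raise ValueError("branch_noise_sigma must be >= 0")


# ---------------------------------------------------------------------------
# Site report


@dataclass
class SiteRow:
    site_index: int
    max_pp: float | None = None
    best_cutoff: float | None = None
    best_scenario_id: str | None = None
    n_transitions: int | None = None
    threshold_upper: float | None = None
    threshold_lower: float | None = None
    call: str = "skipped_gaps"

    def __post_init__(self):
        if self.call not in CALL_VALUES:
            raise ValueError(f"invalid call {self.call!r}")
        if self.max_pp is not None and not 0 <= self.max_pp <= 1:
            raise ValueError(f"max_pp out of [0,1]: {self.max_pp}")


@dataclass
class SiteReport:
    """One row per alignment column; the table behind the Manhattan plot."""

    rows: list[SiteRow] = field(default_factory=list)

    COLUMNS = (
        "site_index",
        "max_pp",
        "best_cutoff",
        "best_scenario_id",
        "n_transitions",
        "threshold_upper",
        "threshold_lower",
        "call",
    )

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def row(self, site_index: int) -> SiteRow:
        for r in self.rows:
            if r.site_index == site_index:
                return r
        raise KeyError(site_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{c: getattr(r, c) for c in self.COLUMNS} for r in self.rows]
        )

    def calls(self) -> dict[int, str]:
        return {r.site_index: r.call for r in self.rows}


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_site_report(report: SiteReport, path: str | Path) -> None:
    """Write the report TSV (floats at 6 significant digits, '' for absent)."""
    with open(path, "w") as fh:
        fh.write("\t".join(SiteReport.COLUMNS) + "\n")
        for row in report.rows:
            fh.write(
                "\t".join(_fmt(getattr(row, c)) for c in SiteReport.COLUMNS) + "\n"
            )


def read_site_report(path: str | Path) -> SiteReport:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != list(SiteReport.COLUMNS):
        raise ValueError(f"unexpected report columns: {list(df.columns)}")
    rows = []
    for rec in df.to_dict("records"):
        def opt(name, conv):
            v = rec[name]
            return conv(v) if v != "" else None

        rows.append(
            SiteRow(
                site_index=int(rec["site_index"]),
                max_pp=opt("max_pp", float),
                best_cutoff=opt("best_cutoff", float),
                best_scenario_id=opt("best_scenario_id", str),
                n_transitions=opt("n_transitions", int),
                threshold_upper=opt("threshold_upper", float),
                threshold_lower=opt("threshold_lower", float),
                call=rec["call"],
            )
        )
    return SiteReport(rows)
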