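"""Paired-chain TCR clonotype calling from single-cell V(D)J contig tables.

The unit of analysis is the *cell*: each assembled contig row describes one
TCR chain (TRA or TRB) recovered from one cell barcode.  A cell enters the
repertoire only if it carries both a productive alpha and a productive beta
chain; cells are then collapsed into clonotypes by exact identity of the
paired receptor (by default the CDR3 nucleotide sequence plus V and J gene
calls of both chains, the 10x Cell Ranger convention).

Two input dialects are supported: the 10x ``filtered_contig_annotations``
CSV and the AIRR Rearrangement TSV.  Both are flat tables read with pandas;
only the columns named in :data:`TENX_COLUMNS` / :data:`AIRR_COLUMNS` are
required.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("tregprov")

__all__ = [
    "Dialect",
    "KeyLevel",
    "ContigRecord",
    "PairedCell",
    "ChainDescriptor",
    "ClonotypeKey",
    "Clonotype",
    "Repertoire",
    "ParseReport",
    "FilterReport",
    "read_contig_table",
    "write_contig_table",
    "filter_paired_productive",
    "call_clonotypes",
    "write_clonotype_table",
    "read_clonotype_table",
]


class Dialect(str, Enum):
    """Supported contig-table file dialects."""

    TENX_CSV = "tenx"
    AIRR_TSV = "airr"


class KeyLevel(str, Enum):
    """Sequence level at which clonotype identity is defined."""

    NT = "nt"
    AA = "aa"


#: mandatory columns per dialect (input order is irrelevant)
TENX_COLUMNS = [
    "barcode",
    "chain",
    "cdr3",
    "cdr3_nt",
    "v_gene",
    "j_gene",
    "productive",
    "umis",
    "reads",
]
AIRR_COLUMNS = [
    "cell_id",
    "locus",
    "junction",
    "junction_aa",
    "v_call",
    "j_call",
    "productive",
    "duplicate_count",
]

_TCR_LOCI = ("TRA", "TRB")
_TRUE_STRINGS = {"true", "t", "1", "yes"}
_FALSE_STRINGS = {"false", "f", "0", "no", "none", ""}

_BARCODE_SUFFIX = re.compile(r"-\d+$")


class ContigTableFormatError(ValueError):
    """A mandatory column is missing or the file is empty."""


def _parse_productive(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise ContigTableFormatError(f"unparseable productive flag: {value!r}")


def strip_barcode_suffix(barcode: str) -> str:
    """Drop a trailing GEM-well suffix such as ``-1`` from a cell barcode."""
    return _BARCODE_SUFFIX.sub("", barcode)


@dataclass(frozen=True, slots=True)
class ContigRecord:
    """One assembled V(D)J contig for one cell."""

    cell_barcode: str
    sample_id: str
    tissue: str
    locus: str  # "TRA" or "TRB"
    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    productive: bool
    umi_count: int
    read_count: int

    def __post_init__(self):
        if self.locus not in _TCR_LOCI:
            raise ValueError(f"locus must be TRA or TRB, got {self.locus!r}")
        if self.productive and not self.cdr3_nt:
            raise ValueError("productive contig with empty cdr3_nt")
        if self.umi_count < 0 or self.read_count < 0:
            raise ValueError("negative counts")


@dataclass(frozen=True, slots=True)
class ChainDescriptor:
    """The receptor-defining fields of one chain."""

    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str


@dataclass(frozen=True, slots=True)
class PairedCell:
    """A cell resolved to exactly one productive alpha and one beta chain."""

    cell_barcode: str
    sample_id: str
    tissue: str
    alpha: ChainDescriptor
    beta: ChainDescriptor


@dataclass(frozen=True, slots=True)
class ClonotypeKey:
    """Identity of a paired receptor at a configured sequence level.

    Two cells belong to the same clonotype iff their alpha components are
    equal AND their beta components are equal.
    """

    alpha_component: str
    beta_component: str
    key_level: KeyLevel
    include_vj: bool

    @classmethod
    def from_cell(
        cls, cell: PairedCell, key_level: KeyLevel = KeyLevel.NT, include_vj: bool = True
    ) -> "ClonotypeKey":
        def component(chain: ChainDescriptor) -> str:
            seq = chain.cdr3_nt if key_level is KeyLevel.NT else chain.cdr3_aa
            if include_vj:
                return f"{chain.v_gene}|{chain.j_gene}|{seq}"
            return seq

        return cls(component(cell.alpha), component(cell.beta), key_level, include_vj)

    def config(self) -> tuple[KeyLevel, bool]:
        return (self.key_level, self.include_vj)


@dataclass(slots=True)
class Clonotype:
    key: ClonotypeKey
    members: frozenset[str]  # cell barcodes
    #: representative chains (from an arbitrary but deterministic member)
    alpha: ChainDescriptor
    beta: ChainDescriptor

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(slots=True)
class Repertoire:
    """All clonotypes of one sample.

    ``n_cells == 0`` with no clonotypes is the explicit empty marker
    returned for an empty input; every statistic downstream rejects it.
    """

    sample_id: str
    tissue: str
    clonotypes: list[Clonotype]

    @property
    def n_cells(self) -> int:
        return sum(c.size for c in self.clonotypes)

    @property
    def n_clonotypes(self) -> int:
        return len(self.clonotypes)

    @property
    def is_empty(self) -> bool:
        return not self.clonotypes

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.clonotypes]

    def key_config(self) -> tuple[KeyLevel, bool] | None:
        return self.clonotypes[0].key.config() if self.clonotypes else None

    def keys(self) -> set[ClonotypeKey]:
        return {c.key for c in self.clonotypes}


@dataclass(slots=True)
class ParseReport:
    n_rows: int = 0
    n_records: int = 0
    n_dropped_non_tcr: int = 0
    n_dropped_missing_barcode: int = 0

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_records": self.n_records,
            "n_dropped_non_tcr": self.n_dropped_non_tcr,
            "n_dropped_missing_barcode": self.n_dropped_missing_barcode,
        }


@dataclass(slots=True)
class FilterReport:
    n_input_cells: int = 0
    n_retained: int = 0
    n_dropped_unpaired: int = 0
    n_multi_chain_resolved: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input_cells": self.n_input_cells,
            "n_retained": self.n_retained,
            "n_dropped_unpaired": self.n_dropped_unpaired,
            "n_multi_chain_resolved": self.n_multi_chain_resolved,
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ContigTableFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )


def read_contig_table(
    path,
    dialect: Dialect | str,
    *,
    sample_id: str | None = None,
    tissue: str | None = None,
) -> tuple[list[ContigRecord], ParseReport]:
    """Read a contig annotation table into :class:`ContigRecord` rows.

    Non-TRA/TRB loci (IGH, IGK, TRG, ...) and rows with a missing cell
    barcode are dropped and counted in the returned :class:`ParseReport`.
    Sample identity comes from a ``sample_id`` column if present, else from
    the ``sample_id`` argument; it is never derived from the barcode.
    """
    dialect = Dialect(dialect)
    path = Path(path)
    sep = "," if dialect is Dialect.TENX_CSV else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ContigTableFormatError(f"{path}: empty file") from None
    if df.empty and df.columns.empty:
        raise ContigTableFormatError(f"{path}: empty file")

    if dialect is Dialect.TENX_CSV:
        _require_columns(df, TENX_COLUMNS, path)
        colmap = dict(
            barcode="barcode", locus="chain", cdr3_aa="cdr3", cdr3_nt="cdr3_nt",
            v_gene="v_gene", j_gene="j_gene", productive="productive",
            umis="umis", reads="reads",
        )
    else:
        _require_columns(df, AIRR_COLUMNS, path)
        colmap = dict(
            barcode="cell_id", locus="locus", cdr3_aa="junction_aa",
            cdr3_nt="junction", v_gene="v_call", j_gene="j_call",
            productive="productive", umis="duplicate_count", reads="consensus_count",
        )

    report = ParseReport(n_rows=len(df))
    records: list[ContigRecord] = []
    have_sample_col = "sample_id" in df.columns
    have_tissue_col = "tissue" in df.columns
    reads_col = colmap["reads"] if colmap["reads"] in df.columns else None

    for row in df.itertuples(index=False):
        row = row._asdict()
        locus = str(row[colmap["locus"]]).strip()
        if locus not in _TCR_LOCI:
            report.n_dropped_non_tcr += 1
            continue
        barcode = str(row[colmap["barcode"]]).strip()
        if not barcode:
            report.n_dropped_missing_barcode += 1
            continue
        records.append(
            ContigRecord(
                cell_barcode=strip_barcode_suffix(barcode),
                sample_id=str(row["sample_id"]) if have_sample_col else (sample_id or "sample"),
                tissue=str(row["tissue"]) if have_tissue_col else (tissue or ""),
                locus=locus,
                cdr3_nt=str(row[colmap["cdr3_nt"]]).strip(),
                cdr3_aa=str(row[colmap["cdr3_aa"]]).strip(),
                v_gene=str(row[colmap["v_gene"]]).strip(),
                j_gene=str(row[colmap["j_gene"]]).strip(),
                productive=_parse_productive(row[colmap["productive"]]),
                umi_count=int(float(row[colmap["umis"]] or 0)),
                read_count=int(float(row[reads_col] or 0)) if reads_col else 0,
            )
        )
    report.n_records = len(records)
    dropped = report.n_dropped_non_tcr + report.n_dropped_missing_barcode
    if dropped:
        logger.info("read_contig_table: dropped %d of %d rows", dropped, report.n_rows)
    return records, report


def write_contig_table(records: Iterable[ContigRecord], path, dialect: Dialect | str) -> None:
    """Write records back out in either dialect (LF endings, fixed columns)."""
    dialect = Dialect(dialect)
    rows = []
    for r in records:
        if dialect is Dialect.TENX_CSV:
            rows.append({
                "barcode": r.cell_barcode, "sample_id": r.sample_id,
                "tissue": r.tissue, "chain": r.locus, "cdr3": r.cdr3_aa,
                "cdr3_nt": r.cdr3_nt, "v_gene": r.v_gene, "j_gene": r.j_gene,
                "productive": "True" if r.productive else "False",
                "umis": r.umi_count, "reads": r.read_count,
            })
        else:
            rows.append({
                "cell_id": r.cell_barcode, "sample_id": r.sample_id,
                "tissue": r.tissue, "locus": r.locus, "junction": r.cdr3_nt,
                "junction_aa": r.cdr3_aa, "v_call": r.v_gene, "j_call": r.j_gene,
                "productive": "T" if r.productive else "F",
                "duplicate_count": r.umi_count, "consensus_count": r.read_count,
            })
    sep = "," if dialect is Dialect.TENX_CSV else "\t"
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# pairing and clonotype calling
# ---------------------------------------------------------------------------

def _dominant_contig(contigs: list[ContigRecord]) -> ContigRecord:
    # highest UMI count, ties by read count, then lexicographic cdr3_nt
    return min(contigs, key=lambda c: (-c.umi_count, -c.read_count, c.cdr3_nt))


def filter_paired_productive(
    contigs: Iterable[ContigRecord], policy: str = "keep-dominant"
) -> tuple[list[PairedCell], FilterReport]:
    """Resolve each cell to one productive alpha/beta pair.

    Cells lacking a productive TRA or TRB are dropped.  When a cell has
    several productive contigs of one locus, ``policy`` decides:

    - ``"keep-dominant"`` (default): keep the highest-UMI contig, ties
      broken by read count then lexicographic CDR3 nucleotide sequence;
    - ``"drop-multi"``: drop the whole cell.
    """
    if policy not in ("keep-dominant", "drop-multi"):
        raise ValueError(f"unknown chain-resolution policy: {policy!r}")

    by_cell: dict[tuple[str, str], list[ContigRecord]] = {}
    for c in contigs:
        by_cell.setdefault((c.sample_id, c.cell_barcode), []).append(c)

    report = FilterReport(n_input_cells=len(by_cell))
    cells: list[PairedCell] = []
    for (sample_id, barcode), group in sorted(by_cell.items()):
        alphas = [c for c in group if c.locus == "TRA" and c.productive]
        betas = [c for c in group if c.locus == "TRB" and c.productive]
        if not alphas or not betas:
            report.n_dropped_unpaired += 1
            continue
        multi = len(alphas) > 1 or len(betas) > 1
        if multi:
            if policy == "drop-multi":
                report.n_dropped_unpaired += 1
                continue
            report.n_multi_chain_resolved += 1
        a, b = _dominant_contig(alphas), _dominant_contig(betas)
        cells.append(
            PairedCell(
                cell_barcode=barcode,
                sample_id=sample_id,
                tissue=group[0].tissue,
                alpha=ChainDescriptor(a.v_gene, a.j_gene, a.cdr3_nt, a.cdr3_aa),
                beta=ChainDescriptor(b.v_gene, b.j_gene, b.cdr3_nt, b.cdr3_aa),
            )
        )
    report.n_retained = len(cells)
    return cells, report


def call_clonotypes(
    cells: Sequence[PairedCell],
    key_level: KeyLevel | str = KeyLevel.NT,
    include_vj: bool = True,
) -> Repertoire:
    """Collapse paired cells of one sample into clonotypes.

    All cells must share one ``sample_id`` (the caller partitions by
    sample).  An empty input yields the explicit empty repertoire.
    """
    key_level = KeyLevel(key_level)
    if not cells:
        return Repertoire(sample_id="", tissue="", clonotypes=[])
    sample_ids = {c.sample_id for c in cells}
    if len(sample_ids) > 1:
        raise ValueError(f"cells span multiple samples: {sorted(sample_ids)}")

    groups: dict[ClonotypeKey, list[PairedCell]] = {}
    for cell in cells:
        key = ClonotypeKey.from_cell(cell, key_level, include_vj)
        groups.setdefault(key, []).append(cell)

    clonotypes = [
        Clonotype(
            key=key,
            members=frozenset(c.cell_barcode for c in members),
            alpha=min(members, key=lambda c: c.cell_barcode).alpha,
            beta=min(members, key=lambda c: c.cell_barcode).beta,
        )
        for key, members in groups.items()
    ]
    # deterministic order: descending size, then key strings
    clonotypes.sort(key=lambda c: (-c.size, c.key.alpha_component, c.key.beta_component))
    first = cells[0]
    return Repertoire(sample_id=first.sample_id, tissue=first.tissue, clonotypes=clonotypes)


def partition_by_sample(cells: Iterable[PairedCell]) -> dict[str, list[PairedCell]]:
    """Group paired cells by sample_id, in deterministic sample order."""
    out: dict[str, list[PairedCell]] = {}
    for c in cells:
        out.setdefault(c.sample_id, []).append(c)
    return dict(sorted(out.items()))


def write_clonotype_table(repertoires: Sequence[Repertoire], path) -> None:
    """Write one row per clonotype across samples as TSV."""
    rows = []
    for rep in repertoires:
        for i, c in enumerate(rep.clonotypes, start=1):
            rows.append({
                "sample_id": rep.sample_id,
                "tissue": rep.tissue,
                "clonotype_id": f"{rep.sample_id}_c{i}",
                "size": c.size,
                "alpha_v": c.alpha.v_gene, "alpha_j": c.alpha.j_gene,
                "alpha_cdr3_nt": c.alpha.cdr3_nt, "alpha_cdr3_aa": c.alpha.cdr3_aa,
                "beta_v": c.beta.v_gene, "beta_j": c.beta.j_gene,
                "beta_cdr3_nt": c.beta.cdr3_nt, "beta_cdr3_aa": c.beta.cdr3_aa,
                "key_level": c.key.key_level.value,
                "include_vj": c.key.include_vj,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_clonotype_table(path) -> list[Repertoire]:
    """Rebuild repertoires from a clonotype table written by this module."""
    df = pd.read_csv(path, sep="\t", dtype={"size": int})
    reps = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        clonotypes = []
        for row in sub.itertuples(index=False):
            alpha = ChainDescriptor(row.alpha_v, row.alpha_j, row.alpha_cdr3_nt, row.alpha_cdr3_aa)
            beta = ChainDescriptor(row.beta_v, row.beta_j, row.beta_cdr3_nt, row.beta_cdr3_aa)
            level = KeyLevel(row.key_level)
            include_vj = bool(row.include_vj)

            def comp(ch: ChainDescriptor) -> str:
                seq = ch.cdr3_nt if level is KeyLevel.NT else ch.cdr3_aa
                return f"{ch.v_gene}|{ch.j_gene}|{seq}" if include_vj else seq

            key = ClonotypeKey(comp(alpha), comp(beta), level, include_vj)
            members = frozenset(f"{row.clonotype_id}:{k}" for k in range(row.size))
            clonotypes.append(Clonotype(key=key, members=members, alpha=alpha, beta=beta))
        clonotypes.sort(key=lambda c: (-c.size, c.key.alpha_component, c.key.beta_component))
        tissue = str(sub["tissue"].iloc[0]) if "tissue" in sub else ""
        reps.append(Repertoire(sample_id=str(sample_id), tissue=tissue, clonotypes=clonotypes))
    return reps
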