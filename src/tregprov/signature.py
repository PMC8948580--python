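"""Fold-change gene counting and signature-concordance scoring.

A differential-expression table (gene, log2 fold-change, expressed flag) is
scored against a canonical signature: a set of genes expected up and a set
expected down in the population of interest.  A signature gene is
*concordant* when it is present and expressed in the table and its fold
change points in the anticipated direction beyond a minimum fold threshold.
The headline number is the concordant fraction, reported in percent.

The minimum fold defaults to 1 (any correct-direction change counts); the
2-fold threshold used for volcano-plot gene counting is available through
the same argument.  Gene symbols are matched case-insensitively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("tregprov")

__all__ = [
    "SignatureSet",
    "ConcordanceResult",
    "validate_de_table",
    "count_fold_change_genes",
    "signature_concordance",
    "read_de_table",
    "read_signature",
    "write_signature",
]


@dataclass(frozen=True)
class SignatureSet:
    """Canonical up ("induced") and down ("repressed") gene sets."""

    up_genes: frozenset[str]
    down_genes: frozenset[str]

    def __post_init__(self):
        up = frozenset(g.casefold() for g in self.up_genes)
        down = frozenset(g.casefold() for g in self.down_genes)
        clash = up & down
        if clash:
            raise ValueError(f"genes in both up and down sets: {sorted(clash)}")
        object.__setattr__(self, "up_genes", up)
        object.__setattr__(self, "down_genes", down)

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


@dataclass(frozen=True)
class ConcordanceResult:
    n_signature_present: int
    n_concordant: int
    fraction_pct: float
    verdicts: pd.DataFrame  # gene, direction, present, expressed, log2fc, concordant

    def to_dict(self) -> dict:
        return {
            "n_signature_present": self.n_signature_present,
            "n_concordant": self.n_concordant,
            "fraction_pct": self.fraction_pct,
        }


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (gene, log2fc, expressed) contract and normalise symbols.

    Gene symbols must be unique after case-normalisation; a missing
    ``expressed`` column defaults to all-True.
    """
    missing = [c for c in ("gene", "log2fc") if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing column(s): {', '.join(missing)}")
    df = table.copy()
    df["gene"] = df["gene"].astype(str).str.casefold()
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].unique()[:5]
        raise ValueError(f"duplicate gene symbols after case-normalization: {list(dupes)}")
    df["log2fc"] = df["log2fc"].astype(float)
    if "expressed" not in df.columns:
        df["expressed"] = True
    df["expressed"] = df["expressed"].astype(bool)
    return df


def count_fold_change_genes(
    table: pd.DataFrame, fold_threshold: float = 2.0, direction: str = "both"
) -> int:
    """Number of expressed genes changing by more than ``fold_threshold``.

    ``direction`` is ``"up"`` (log2fc > log2(threshold)), ``"down"``
    (log2fc < -log2(threshold)) or ``"both"``.
    """
    if not fold_threshold > 1:
        raise ValueError(f"fold threshold must exceed 1, got {fold_threshold}")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    df = validate_de_table(table)
    df = df[df["expressed"]]
    cut = math.log2(fold_threshold)
    up = int((df["log2fc"] > cut).sum())
    down = int((df["log2fc"] < -cut).sum())
    return {"up": up, "down": down, "both": up + down}[direction]


def signature_concordance(
    table: pd.DataFrame,
    signature: SignatureSet,
    min_fold: float = 1.0,
    denominator: str = "present",
) -> ConcordanceResult:
    """Fraction of signature genes changing in the anticipated direction.

    A gene is concordant iff present and expressed in the table AND its
    log2fc exceeds log2(min_fold) in the expected direction.  With the
    default ``denominator="present"`` the fraction is taken over signature
    genes found in the table; ``denominator="all"`` uses the full signature.
    """
    if len(signature) == 0:
        raise ValueError("empty signature")
    if not min_fold >= 1:
        raise ValueError(f"min_fold must be >= 1, got {min_fold}")
    if denominator not in ("present", "all"):
        raise ValueError(f"denominator must be 'present' or 'all', got {denominator!r}")
    df = validate_de_table(table).set_index("gene")
    cut = math.log2(min_fold)

    rows = []
    for gene, direction in sorted(
        [(g, "up") for g in signature.up_genes] + [(g, "down") for g in signature.down_genes]
    ):
        present = gene in df.index
        expressed = bool(df.at[gene, "expressed"]) if present else False
        log2fc = float(df.at[gene, "log2fc"]) if present else float("nan")
        if present and expressed:
            concordant = log2fc > cut if direction == "up" else log2fc < -cut
        else:
            concordant = False
        rows.append({
            "gene": gene, "direction": direction, "present": present,
            "expressed": expressed, "log2fc": log2fc, "concordant": concordant,
        })
    verdicts = pd.DataFrame(rows)
    n_absent = int((~verdicts["present"]).sum())
    if n_absent:
        logger.info("signature_concordance: %d signature gene(s) absent from table", n_absent)

    if denominator == "present":
        n_denom = int(verdicts["present"].sum())
    else:
        n_denom = len(verdicts)
    n_concordant = int(verdicts["concordant"].sum())
    if n_denom == 0:
        raise ValueError("no signature genes present in the DE table")
    return ConcordanceResult(
        n_signature_present=n_denom,
        n_concordant=n_concordant,
        fraction_pct=100.0 * n_concordant / n_denom,
        verdicts=verdicts,
    )


def read_de_table(path) -> pd.DataFrame:
    """Read a (gene, log2fc[, expressed]) TSV and validate it."""
    return validate_de_table(pd.read_csv(path, sep="\t"))


def read_signature(path) -> SignatureSet:
    """Read a two-column (gene, direction in {up, down}) TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "direction") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise ValueError(f"{path}: invalid direction value(s): {sorted(bad)}")
    return SignatureSet(
        up_genes=frozenset(df.loc[df["direction"] == "up", "gene"].astype(str)),
        down_genes=frozenset(df.loc[df["direction"] == "down", "gene"].astype(str)),
    )


def write_signature(signature: SignatureSet, path) -> None:
    rows = [{"gene": g, "direction": "up"} for g in sorted(signature.up_genes)]
    rows += [{"gene": g, "direction": "down"} for g in sorted(signature.down_genes)]
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
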