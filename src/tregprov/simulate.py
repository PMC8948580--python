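"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator draws from its own seeded ``numpy.random.Generator`` stream,
so adding one generator never shifts another's output, and identical
model + seed yields byte-identical files (LF endings, fixed column order).

What is emulated
----------------
* **Repertoires** — cells with one productive TRA and one productive TRB
  contig each, collapsed into clonotypes whose size distribution follows a
  configurable abundance model (explicit sizes, symmetric Dirichlet, or a
  rank power law).  Optional fractions of unpaired and extra-chain cells
  exercise the pairing filter; clonotype keys can be planted into a second
  sample to exercise overlap statistics.  CDR3 nucleotide sequences are
  uniform random codons (no stop codons) between a TGT leader and TTT
  terminator, giving the canonical C...F junction; collisions are rejected
  so key uniqueness is guaranteed.  Biological realism of V(D)J
  recombination is a non-goal.
* **Parabiosis cohorts** — blood chimerism per mouse from a truncated
  Gaussian; tissue chimerism = blood x true recruitment fraction plus
  Gaussian noise, floored at zero.
* **Photoconversion panels** — organ photoconverted fractions equal to the
  nondraining-reference fraction times planted enrichment factors, plus
  optional noise.
* **DE tables** — an exact planted number of signature genes concordant
  (round(fraction x n_signature)); concordant genes get a correct-direction
  log2 fold change centred on the effect size, discordant genes the flipped
  sign, background genes are centred on zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .provenance import ParabiosisMouse, PhotoconversionSample
from .repertoire import ContigRecord, Dialect, write_contig_table
from .signature import SignatureSet, write_signature

__all__ = [
    "ExplicitSizes",
    "DirichletAbundance",
    "PowerLawAbundance",
    "RepertoireModel",
    "ParabiosisModel",
    "SignatureModel",
    "RepertoireTruth",
    "ParabiosisTruth",
    "PhotoconversionTruth",
    "SignatureTruth",
    "simulate_repertoire",
    "simulate_parabiosis",
    "simulate_photoconversion",
    "simulate_de_table",
]

_NT = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = sorted(
    a + b + c for a in _NT for b in _NT for c in _NT if a + b + c not in _STOPS
)


# ---------------------------------------------------------------------------
# abundance models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExplicitSizes:
    """Clone sizes given verbatim; must sum to the model's n_cells."""

    sizes: tuple[int, ...]

    def draw(self, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        sizes = np.asarray(self.sizes, dtype=int)
        if sizes.sum() != n_cells:
            raise ValueError(
                f"explicit sizes sum to {sizes.sum()}, model n_cells is {n_cells}"
            )
        if np.any(sizes < 1):
            raise ValueError("explicit clone sizes must be positive")
        return sizes


@dataclass(frozen=True)
class DirichletAbundance:
    """Clone proportions ~ symmetric Dirichlet; large concentration -> even."""

    n_clonotypes: int
    concentration: float = 1.0

    def draw(self, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        p = rng.dirichlet(np.full(self.n_clonotypes, self.concentration))
        sizes = rng.multinomial(n_cells, p)
        return sizes[sizes > 0]


@dataclass(frozen=True)
class PowerLawAbundance:
    """Clone proportions proportional to rank^-exponent (skewed repertoires)."""

    n_clonotypes: int
    exponent: float = 1.0

    def draw(self, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        ranks = np.arange(1, self.n_clonotypes + 1, dtype=float)
        p = ranks ** -self.exponent
        p /= p.sum()
        sizes = rng.multinomial(n_cells, p)
        return sizes[sizes > 0]


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepertoireModel:
    """Study design for one simulated repertoire (optionally a shared pair).

    Defaults emulate a tissue Treg sample: a few hundred cells with a
    skewed clone-size distribution containing both singletons and expanded
    clones.
    """

    n_cells: int = 200
    abundance: ExplicitSizes | DirichletAbundance | PowerLawAbundance = field(
        default_factory=lambda: PowerLawAbundance(n_clonotypes=150, exponent=1.0)
    )
    n_shared_planted: int = 0
    cdr3_length_range: tuple[int, int] = (30, 48)  # nt, multiples of 3
    unpaired_fraction: float = 0.0
    multichain_fraction: float = 0.0
    sample_id: str = "sample1"
    second_sample_id: str = "sample2"
    tissue: str = "aorta"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.cdr3_length_range
        if lo % 3 or hi % 3 or lo < 9 or hi < lo:
            raise ValueError("cdr3_length_range must be in-frame (multiples of 3), >= 9")
        if not 0 <= self.unpaired_fraction < 1:
            raise ValueError("unpaired_fraction must be in [0, 1)")
        if not 0 <= self.multichain_fraction < 1:
            raise ValueError("multichain_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ParabiosisModel:
    """Parabiosis cohort design.

    Defaults mirror the published experiment: five mouse pairs, blood
    chimerism around 40% and a true recruitment fraction of 0.786, with
    steady-state and post-injury aortic Treg counts of 20 and 5375.
    Noise standard deviations are in percentage points.
    """

    n_mice: int = 5
    true_recruitment_fraction: float = 0.786
    blood_chimerism_mean: float = 40.0
    blood_chimerism_sd: float = 10.0
    tissue_noise_sd: float = 5.0
    steady_state_count: int = 20
    post_injury_count: int = 5375
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.true_recruitment_fraction <= 1:
            raise ValueError("true_recruitment_fraction must be in [0, 1]")
        if self.n_mice < 1:
            raise ValueError("need at least one mouse")


@dataclass(frozen=True)
class SignatureModel:
    """DE-table design with a planted concordant fraction of signature genes."""

    n_genes: int = 10000
    n_signature: int = 100
    planted_concordant_fraction: float = 0.74
    effect_size_log2: float = 2.0
    noise_sd_log2: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_signature > self.n_genes:
            raise ValueError("n_signature cannot exceed n_genes")
        if not 0 <= self.planted_concordant_fraction <= 1:
            raise ValueError("planted_concordant_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class RepertoireTruth:
    """Ground truth: every downstream statistic is computable from this."""

    #: per sample: clone sizes counting only paired cells (what the pipeline recovers)
    clone_sizes: dict[str, list[int]]
    #: per sample: planted sizes before unpaired-cell removal
    planted_sizes: dict[str, list[int]]
    #: per sample: NT+VJ key components (alpha, beta), parallel to clone_sizes
    keys: dict[str, list[tuple[str, str]]]
    shared_keys: list[tuple[str, str]]
    n_unpaired: dict[str, int]
    n_multichain: dict[str, int]
    files: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "clone_sizes": self.clone_sizes,
            "planted_sizes": self.planted_sizes,
            "keys": self.keys,
            "shared_keys": self.shared_keys,
            "n_unpaired": self.n_unpaired,
            "n_multichain": self.n_multichain,
            "files": self.files,
        }, indent=2) + "\n")


@dataclass
class ParabiosisTruth:
    cohort: list[ParabiosisMouse]
    steady_state_count: int
    post_injury_count: int
    true_recruitment_fraction: float
    files: dict[str, str] = field(default_factory=dict)


@dataclass
class PhotoconversionTruth:
    samples: list[PhotoconversionSample]
    enrichments: list[float]
    reference_fraction: float
    files: dict[str, str] = field(default_factory=dict)


@dataclass
class SignatureTruth:
    de_table: pd.DataFrame
    signature: SignatureSet
    labels: pd.DataFrame  # gene, direction, concordant (planted)
    n_concordant_true: int
    files: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# repertoire generator
# ---------------------------------------------------------------------------

def _random_cdr3_nt(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    lo, hi = length_range
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    middle = rng.choice(len(_CODONS), size=n_codons - 2)
    return "TGT" + "".join(_CODONS[i] for i in middle) + "TTT"


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


@dataclass(frozen=True)
class _Chain:
    v_gene: str
    j_gene: str
    cdr3_nt: str


def _draw_chain(rng, locus: str, length_range, used: set) -> _Chain:
    prefix = "TRA" if locus == "TRA" else "TRB"
    nv = 20 if locus == "TRA" else 31
    nj = 50 if locus == "TRA" else 2
    while True:  # rejection-sample CDR3 collisions so keys stay unique
        chain = _Chain(
            v_gene=f"{prefix}V{int(rng.integers(1, nv + 1))}",
            j_gene=f"{prefix}J{int(rng.integers(1, nj + 1))}",
            cdr3_nt=_random_cdr3_nt(rng, length_range),
        )
        if chain.cdr3_nt not in used:
            used.add(chain.cdr3_nt)
            return chain


def _key_component(chain: _Chain) -> str:
    return f"{chain.v_gene}|{chain.j_gene}|{chain.cdr3_nt}"


def simulate_repertoire(model: RepertoireModel, out_dir=None) -> RepertoireTruth:
    """Generate contig tables (both dialects) plus the truth record.

    When ``model.n_shared_planted > 0`` a second sample of the same design
    is generated that reuses that many clonotype keys from the first, so
    overlap statistics have known truth.  When ``out_dir`` is given, writes
    ``contigs_tenx.csv``, ``contigs_airr.tsv`` and ``truth.json`` there and
    records the paths in the truth; the in-memory records are attached as
    ``truth.records`` either way.
    """
    rng = np.random.default_rng(model.seed)
    used_cdr3: set[str] = set()
    truth = RepertoireTruth(
        clone_sizes={}, planted_sizes={}, keys={}, shared_keys=[],
        n_unpaired={}, n_multichain={},
    )
    records: list[ContigRecord] = []
    cell_counter = 0

    def new_barcode() -> str:
        nonlocal cell_counter
        cell_counter += 1
        bc = "".join(_NT[i] for i in rng.choice(4, size=16))
        return f"{bc}{cell_counter:05d}-1"

    samples = [model.sample_id]
    if model.n_shared_planted > 0:
        samples.append(model.second_sample_id)

    first_clones: list[tuple[_Chain, _Chain]] = []
    for sample_idx, sample_id in enumerate(samples):
        sizes = model.abundance.draw(model.n_cells, rng)
        clones: list[tuple[_Chain, _Chain]] = []
        if sample_idx == 1:
            n_shared = model.n_shared_planted
            if n_shared > min(len(first_clones), len(sizes)):
                raise ValueError(
                    f"cannot plant {n_shared} shared clonotypes: only "
                    f"{min(len(first_clones), len(sizes))} available"
                )
            shared_idx = rng.choice(len(first_clones), size=n_shared, replace=False)
            clones.extend(first_clones[i] for i in sorted(shared_idx))
        while len(clones) < len(sizes):
            clones.append((
                _draw_chain(rng, "TRA", model.cdr3_length_range, used_cdr3),
                _draw_chain(rng, "TRB", model.cdr3_length_range, used_cdr3),
            ))
        if sample_idx == 0:
            first_clones = clones
        else:
            truth.shared_keys = [
                (_key_component(a), _key_component(b)) for a, b in clones[: model.n_shared_planted]
            ]

        # assign cells to clones, then pick which cells lose a chain / gain one
        cell_clone = np.repeat(np.arange(len(sizes)), sizes)
        n_cells = cell_clone.size
        n_unpaired = int(round(model.unpaired_fraction * n_cells))
        n_multi = int(round(model.multichain_fraction * n_cells))
        special = rng.choice(n_cells, size=n_unpaired + n_multi, replace=False)
        unpaired_set = set(special[:n_unpaired].tolist())
        multi_set = set(special[n_unpaired:].tolist())

        paired_sizes = np.zeros(len(sizes), dtype=int)
        for cell_idx in range(n_cells):
            clone_idx = int(cell_clone[cell_idx])
            alpha, beta = clones[clone_idx]
            barcode = new_barcode()
            umi_a, umi_b = int(rng.integers(10, 51)), int(rng.integers(10, 51))

            def contig(chain: _Chain, locus: str, umis: int) -> ContigRecord:
                return ContigRecord(
                    cell_barcode=barcode.rsplit("-", 1)[0],
                    sample_id=sample_id, tissue=model.tissue, locus=locus,
                    cdr3_nt=chain.cdr3_nt, cdr3_aa=_translate(chain.cdr3_nt),
                    v_gene=chain.v_gene, j_gene=chain.j_gene, productive=True,
                    umi_count=umis, read_count=umis * 12,
                )

            records.append(contig(alpha, "TRA", umi_a))
            if cell_idx in unpaired_set:
                continue  # alpha-only cell: dropped by the pairing filter
            records.append(contig(beta, "TRB", umi_b))
            paired_sizes[clone_idx] += 1
            if cell_idx in multi_set:
                # secondary beta with strictly lower UMI: resolved away by
                # the keep-dominant policy
                extra = _draw_chain(rng, "TRB", model.cdr3_length_range, used_cdr3)
                records.append(contig(extra, "TRB", int(rng.integers(1, 10))))

        keep = paired_sizes > 0
        truth.planted_sizes[sample_id] = np.asarray(sizes, dtype=int).tolist()
        truth.clone_sizes[sample_id] = paired_sizes[keep].tolist()
        truth.keys[sample_id] = [
            (_key_component(a), _key_component(b))
            for (a, b), k in zip(clones, keep) if k
        ]
        truth.n_unpaired[sample_id] = n_unpaired
        truth.n_multichain[sample_id] = n_multi

    truth.records = records  # type: ignore[attr-defined]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tenx, airr = out_dir / "contigs_tenx.csv", out_dir / "contigs_airr.tsv"
        write_contig_table(records, tenx, Dialect.TENX_CSV)
        write_contig_table(records, airr, Dialect.AIRR_TSV)
        truth.files = {"tenx": str(tenx), "airr": str(airr)}
        truth.to_json(out_dir / "truth.json")
        truth.files["truth"] = str(out_dir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# parabiosis / photoconversion / DE generators
# ---------------------------------------------------------------------------

def simulate_parabiosis(model: ParabiosisModel, out_dir=None) -> ParabiosisTruth:
    """Draw a parabiosis cohort with a known true recruitment fraction."""
    rng = np.random.default_rng(model.seed)
    cohort = []
    for i in range(model.n_mice):
        while True:  # truncate blood chimerism to (0, 100]
            blood = rng.normal(model.blood_chimerism_mean, model.blood_chimerism_sd)
            if 0 < blood <= 100:
                break
        tissue = blood * model.true_recruitment_fraction
        if model.tissue_noise_sd > 0:
            tissue += rng.normal(0.0, model.tissue_noise_sd)
        tissue = max(tissue, 0.0)
        cohort.append(ParabiosisMouse(f"mouse{i + 1:03d}", float(blood), float(tissue)))

    truth = ParabiosisTruth(
        cohort=cohort,
        steady_state_count=model.steady_state_count,
        post_injury_count=model.post_injury_count,
        true_recruitment_fraction=model.true_recruitment_fraction,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "cohort.csv"
        pd.DataFrame(
            [{"mouse_id": m.mouse_id,
              "blood_chimerism_pct": m.blood_chimerism_pct,
              "tissue_chimerism_pct": m.tissue_chimerism_pct} for m in cohort]
        ).to_csv(path, index=False, lineterminator="\n")
        (out_dir / "truth.json").write_text(json.dumps({
            "true_recruitment_fraction": model.true_recruitment_fraction,
            "steady_state_count": model.steady_state_count,
            "post_injury_count": model.post_injury_count,
        }, indent=2) + "\n")
        truth.files = {"cohort": str(path), "truth": str(out_dir / "truth.json")}
    return truth


def simulate_photoconversion(
    reference_fraction: float = 0.01,
    enrichments: Sequence[float] = (0.5, 3.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    organs: Sequence[str] | None = None,
    reference_organ: str = "ALN",
    out_dir=None,
) -> PhotoconversionTruth:
    """Organ photoconverted fractions = reference x planted enrichments.

    The nondraining reference organ is emitted noise-free; test organs get
    optional additive Gaussian noise, clipped to [0, 1].
    """
    if not reference_fraction > 0:
        raise ValueError("reference_fraction must be positive")
    enrichments = [float(e) for e in enrichments]
    if any(e <= 0 for e in enrichments):
        raise ValueError("enrichment factors must be positive")
    if organs is None:
        organs = [f"organ{i + 1}" for i in range(len(enrichments))]
    if len(organs) != len(enrichments):
        raise ValueError("organs and enrichments must have equal length")

    rng = np.random.default_rng(seed)
    samples = [PhotoconversionSample(reference_organ, reference_fraction, True)]
    for organ, enr in zip(organs, enrichments):
        frac = reference_fraction * enr
        if noise_sd > 0:
            frac += rng.normal(0.0, noise_sd)
        samples.append(PhotoconversionSample(organ, float(np.clip(frac, 0.0, 1.0)), False))

    truth = PhotoconversionTruth(
        samples=samples, enrichments=enrichments, reference_fraction=reference_fraction
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "photoconversion.csv"
        pd.DataFrame(
            [{"organ": s.organ, "phc_fraction": s.phc_fraction,
              "is_nondraining_reference": s.is_nondraining_reference} for s in samples]
        ).to_csv(path, index=False, lineterminator="\n")
        truth.files = {"samples": str(path)}
    return truth


def simulate_de_table(model: SignatureModel, out_dir=None) -> SignatureTruth:
    """DE table + signature with an exact planted number of concordant genes.

    Exactly ``round(planted_concordant_fraction * n_signature)`` signature
    genes receive a correct-direction fold change; the rest are flipped.
    In noise-free mode the measured concordance at min_fold=1 therefore
    equals the planted fraction exactly.
    """
    rng = np.random.default_rng(model.seed)
    genes = [f"gene{i + 1:05d}" for i in range(model.n_genes)]
    sig_idx = rng.choice(model.n_genes, size=model.n_signature, replace=False)
    sig_genes = [genes[i] for i in sorted(sig_idx)]
    is_up = rng.random(model.n_signature) < 0.5

    n_conc = int(round(model.planted_concordant_fraction * model.n_signature))
    conc_idx = set(rng.choice(model.n_signature, size=n_conc, replace=False).tolist())

    log2fc = rng.normal(0.0, model.noise_sd_log2, size=model.n_genes) \
        if model.noise_sd_log2 > 0 else np.zeros(model.n_genes)
    labels = []
    gene_pos = {g: i for i, g in enumerate(genes)}
    for j, gene in enumerate(sig_genes):
        direction = "up" if is_up[j] else "down"
        concordant = j in conc_idx
        sign = (1 if direction == "up" else -1) * (1 if concordant else -1)
        log2fc[gene_pos[gene]] += sign * model.effect_size_log2
        labels.append({"gene": gene, "direction": direction, "concordant": concordant})

    de = pd.DataFrame({"gene": genes, "log2fc": log2fc, "expressed": True})
    signature = SignatureSet(
        up_genes=frozenset(l["gene"] for l in labels if l["direction"] == "up"),
        down_genes=frozenset(l["gene"] for l in labels if l["direction"] == "down"),
    )
    truth = SignatureTruth(
        de_table=de, signature=signature,
        labels=pd.DataFrame(labels), n_concordant_true=n_conc,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        de_path, sig_path = out_dir / "de_table.tsv", out_dir / "signature.tsv"
        de.to_csv(de_path, sep="\t", index=False, lineterminator="\n")
        write_signature(signature, sig_path)
        truth.files = {"de": str(de_path), "signature": str(sig_path)}
    return truth
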