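import pytest

from tregprov.repertoire import (
    ChainDescriptor,
    Clonotype,
    ClonotypeKey,
    ContigRecord,
    KeyLevel,
    Repertoire,
)

_counter = [0]


def make_key(label: str, key_level=KeyLevel.NT, include_vj=True) -> ClonotypeKey:
    """A distinct clonotype key per label, at the default configuration."""
    return ClonotypeKey(f"TRAV1|TRAJ1|TGT{label}TTT", f"TRBV1|TRBJ1|TGC{label}TTC",
                        key_level, include_vj)


def make_repertoire(sizes, sample_id="s1", tissue="aorta", labels=None,
                    key_level=KeyLevel.NT) -> Repertoire:
    """Build a repertoire with the given clone sizes and optional key labels."""
    clonotypes = []
    for i, size in enumerate(sizes):
        label = labels[i] if labels else f"{sample_id}AAA{i:04d}"
        key = make_key(label, key_level)
        members = frozenset(f"{sample_id}bc{i}_{j}" for j in range(size))
        chain = ChainDescriptor("TRAV1", "TRAJ1", f"TGT{label}TTT", "CXF")
        clonotypes.append(Clonotype(key=key, members=members, alpha=chain, beta=chain))
    return Repertoire(sample_id=sample_id, tissue=tissue, clonotypes=clonotypes)


def make_contig(barcode, locus="TRA", cdr3_nt="TGTGCAAGATTT", productive=True,
                umis=10, reads=100, sample_id="s1", v_gene=None, j_gene=None):
    prefix = locus if locus in ("TRA", "TRB") else "TRA"
    return ContigRecord(
        cell_barcode=barcode, sample_id=sample_id, tissue="aorta", locus=locus,
        cdr3_nt=cdr3_nt, cdr3_aa="CARF", v_gene=v_gene or f"{prefix}V1",
        j_gene=j_gene or f"{prefix}J1", productive=productive,
        umi_count=umis, read_count=reads,
    )


@pytest.fixture
def tenx_csv(tmp_path):
    """Minimal hand-written 10x contig CSV: TRA + TRB for one cell, one IGH."""
    path = tmp_path / "contigs.csv"
    path.write_text(
        "barcode,chain,cdr3,cdr3_nt,v_gene,j_gene,productive,umis,reads\n"
        "AAACCTGA-1,TRA,CAVRF,TGTGCAGTTAGATTT,TRAV1,TRAJ33,True,5,50\n"
        "AAACCTGA-1,TRB,CASSF,TGTGCCAGCAGTTTT,TRBV19,TRBJ2-7,True,7,70\n"
        "AAACCTGA-1,IGH,CARDF,TGTGCGAGAGATTTT,IGHV1,IGHJ4,True,3,30\n"
    )
    return path


@pytest.fixture
def airr_tsv(tmp_path):
    """Minimal AIRR rearrangement TSV, one row non-productive."""
    path = tmp_path / "rearrangements.tsv"
    rows = [
        "cell_id\tlocus\tjunction\tjunction_aa\tv_call\tj_call\tproductive\tduplicate_count",
        "cellA\tTRA\tTGTGCAGTTAGATTT\tCAVRF\tTRAV1\tTRAJ33\tT\t5",
        "cellA\tTRB\tTGTGCCAGCAGTTTT\tCASSF\tTRBV19\tTRBJ2-7\tT\t7",
        "cellB\tTRA\tTGTGCAATGAGATTT\tCAMRF\tTRAV2\tTRAJ12\tT\t4",
        "cellB\tTRB\tTGTGCCTGGAGTTTT\tCAWSF\tTRBV5\tTRBJ1-1\tF\t2",
    ]
    path.write_text("\n".join(rows) + "\n")
    return path
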