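"""Codon reconstruction, Nei-Gojobori site accounting, pN/pS, and SAAV
calling with BLOSUM62 scores."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from codivkit.codon_variants import (
    GeneModel,
    call_saavs,
    codon_counts_from_alleles,
    gene_pnps,
    ng_site_counts,
    read_blosum,
    read_gene_models,
    saav_occurrence,
    translate_codon,
    write_blosum,
    write_gene_models,
)
from codivkit.snv_profiles import NUCLEOTIDES, AlleleCountMatrix

SENSE = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]


def brute_force_site_counts(codon):
    """Independent oracle: enumerate all 9 single-nucleotide neighbors and
    translate with Biopython."""
    aa = str(Seq(codon).translate())
    syn = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            neighbor = codon[:pos] + nt + codon[pos + 1 :]
            if str(Seq(neighbor).translate()) == aa:
                syn += 1 / 3
    return syn, 3 - syn


def test_site_counts_match_neighbor_enumeration_for_all_sense_codons():
    for codon in SENSE:
        assert ng_site_counts(codon) == pytest.approx(
            brute_force_site_counts(codon), abs=1e-12
        )


@pytest.mark.parametrize(
    "codon, syn",
    [
        ("TTT", 1 / 3),  # Phe: only TTC is synonymous
        ("TGG", 0.0),  # Trp has no synonymous neighbor
        ("GGG", 1.0),  # 4-fold degenerate third position
    ],
)
def test_site_count_examples(codon, syn):
    s, n = ng_site_counts(codon)
    assert s == pytest.approx(syn, abs=1e-12)
    assert s + n == pytest.approx(3.0, abs=1e-12)


def test_site_counts_reject_stop_codons():
    with pytest.raises(ValueError):
        ng_site_counts("TAA")


def _acm_for_gene(seq, per_position_counts, samples=("s0",)):
    """Build an allele-count matrix whose positions exactly span ``seq``."""
    n = len(seq)
    counts = np.zeros((n, len(samples), 4), dtype=int)
    for i in range(n):
        for j in range(len(samples)):
            for nt, k in per_position_counts(i, j, seq[i]).items():
                counts[i, j, NUCLEOTIDES.index(nt)] = k
    return AlleleCountMatrix(
        positions=np.arange(n), samples=list(samples), counts=counts
    )


def _gene(seq, gene_id="g1", strand="+"):
    return GeneModel(
        gene_id=gene_id, contig="c", start=0, end=len(seq), strand=strand, seq=seq
    )


def test_monomorphic_codon_reconstruction():
    seq = "ATGGGG"
    acm = _acm_for_gene(seq, lambda i, j, ref: {ref: 100})
    table = codon_counts_from_alleles(acm, [_gene(seq)])
    first = table.records[table.records["codon_index"] == 0]
    assert first["codon"].tolist() == ["ATG"]
    assert first["count"].tolist() == [100]
    assert first["coverage"].tolist() == [100]


def test_single_variable_position_split_reconstruction():
    seq = "TTTGGG"

    def counts(i, j, ref):
        if i == 2:
            return {"T": 70, "C": 30}
        return {ref: 100}

    acm = _acm_for_gene(seq, counts)
    table = codon_counts_from_alleles(acm, [_gene(seq)])
    first = table.records[table.records["codon_index"] == 0]
    got = dict(zip(first["codon"], first["count"]))
    assert got == {"TTT": 70, "TTC": 30}


def test_two_variable_positions_flagged_ambiguous_and_excluded():
    seq = "TTTGGG"

    def counts(i, j, ref):
        if i in (1, 2):
            return {ref: 70, "A": 30}
        return {ref: 100}

    acm = _acm_for_gene(seq, counts)
    table = codon_counts_from_alleles(acm, [_gene(seq)])
    assert len(table.ambiguous) == 1
    assert table.ambiguous.iloc[0]["codon_index"] == 0
    assert set(table.records["codon_index"]) == {1}
    result = gene_pnps(table, _gene(seq))
    # only the unambiguous codon contributes to site counts
    assert result.n_sites + result.s_sites == pytest.approx(3.0)


def test_reverse_strand_gene_reverse_complemented_before_framing():
    # genomic forward strand CATCCC reads ATG GGG on the reverse strand... the
    # reverse complement of CCCATG... build explicitly:
    gene_seq = "ATGGGG"
    genomic = str(Seq(gene_seq).reverse_complement())  # CCCCAT
    acm = _acm_for_gene(genomic, lambda i, j, ref: {ref: 50})
    table = codon_counts_from_alleles(acm, [_gene(gene_seq, strand="-")])
    assert table.records["codon"].tolist() == ["ATG", "GGG"]


@pytest.mark.parametrize(
    "variant_nt, expected",
    [
        ("C", dict(n_obs=0, s_obs=1, pnps=0.0)),  # TTT->TTC synonymous
        ("A", dict(n_obs=1, s_obs=0, pnps=float("inf"))),  # TTT->TTA Phe->Leu
    ],
)
def test_pnps_single_variant_classification(variant_nt, expected):
    seq = "TTTGGG"

    def counts(i, j, ref):
        if i == 2:
            return {"T": 70, variant_nt: 30}
        return {ref: 100}

    table = codon_counts_from_alleles(_acm_for_gene(seq, counts), [_gene(seq)])
    result = gene_pnps(table, _gene(seq))
    assert result.n_obs == expected["n_obs"]
    assert result.s_obs == expected["s_obs"]
    if np.isinf(expected["pnps"]):
        assert np.isinf(result.pnps)
    else:
        assert result.pnps == pytest.approx(expected["pnps"])


def test_pnps_undefined_without_any_variants():
    seq = "TTTGGG"
    table = codon_counts_from_alleles(
        _acm_for_gene(seq, lambda i, j, ref: {ref: 100}), [_gene(seq)]
    )
    result = gene_pnps(table, _gene(seq))
    assert np.isnan(result.pnps)
    assert not result.defined


def test_site_totals_equal_three_per_unambiguous_codon(rng):
    from codivkit.simdata import HoloSimConfig, simulate_hologenome

    sim = simulate_hologenome(
        HoloSimConfig(
            n_hosts_per_cluster=3,
            n_host_sites=20,
            sym_gene_lengths=(8, 10, 12),
            n_cluster_snvs=(3, 5),
            seed=21,
        )
    )
    table = codon_counts_from_alleles(sim.allele_counts, sim.genes)
    for gene in sim.genes:
        sub = table.records[table.records["gene_id"] == gene.gene_id]
        n_codons = sub["codon_index"].nunique()
        r = gene_pnps(table, gene)
        assert r.n_sites + r.s_sites == pytest.approx(3.0 * n_codons, abs=1e-9)


def test_saav_not_called_for_synonymous_codon_split():
    seq = "TTTGGG"

    def counts(i, j, ref):
        if i == 2:
            return {"T": 70, "C": 30}
        return {ref: 100}

    table = codon_counts_from_alleles(_acm_for_gene(seq, counts), [_gene(seq)])
    blosum = substitution_matrices.load("BLOSUM62")
    assert call_saavs(table, blosum) == []


def test_saav_called_with_blosum_score_from_matrix_file(tmp_path):
    seq = "TTTGGG"

    def counts(i, j, ref):
        if i == 2:
            return {"T": 70, "A": 30}  # TTT/TTA -> Phe/Leu
        return {ref: 100}

    table = codon_counts_from_alleles(_acm_for_gene(seq, counts), [_gene(seq)])
    path = tmp_path / "BLOSUM62.txt"
    write_blosum(substitution_matrices.load("BLOSUM62"), path)
    matrix = read_blosum(path)
    saavs = call_saavs(table, matrix, host_clusters={"s0": 1})
    assert len(saavs) == 1
    rec = saavs[0]
    assert (rec.consensus_aa, rec.competing_aa) == ("F", "L")
    assert rec.departure == pytest.approx(0.3)
    assert rec.blosum62 == float(matrix["F"]["L"])
    assert rec.prevalence == {"1": 1.0}


def test_identity_pairs_maximal_in_blosum_rows(tmp_path):
    path = tmp_path / "BLOSUM62.txt"
    write_blosum(substitution_matrices.load("BLOSUM62"), path)
    matrix = read_blosum(path)
    aas = "ARNDCQEGHILKMFPSTWYV"
    for a in aas:
        row_max = max(float(matrix[a][b]) for b in aas)
        assert float(matrix[a][a]) == row_max


def test_saav_frequencies_consistent_with_codon_translation(rng):
    from codivkit.simdata import HoloSimConfig, simulate_hologenome

    sim = simulate_hologenome(
        HoloSimConfig(
            n_hosts_per_cluster=4,
            n_host_sites=20,
            sym_gene_lengths=(15, 15),
            n_cluster_snvs=(4, 6),
            within_host_minor_freq=0.4,
            seed=31,
        )
    )
    table = codon_counts_from_alleles(sim.allele_counts, sim.genes)
    blosum = substitution_matrices.load("BLOSUM62")
    saavs = call_saavs(table, blosum)
    for rec in saavs:
        sub = table.records[
            (table.records["gene_id"] == rec.gene_id)
            & (table.records["codon_index"] == rec.codon_index)
        ]
        aa_counts = {}
        for codon, k in zip(sub["codon"], sub["count"]):
            aa = translate_codon(codon)
            aa_counts[aa] = aa_counts.get(aa, 0) + k
        total = sum(aa_counts.values())
        cons = max(sorted(aa_counts), key=lambda a: aa_counts[a])
        assert cons == rec.consensus_aa
        assert rec.departure == pytest.approx(1 - aa_counts[cons] / total, abs=1e-12)
    if saavs:
        occ = saav_occurrence(table, saavs)
        assert set(occ.to_numpy().ravel()) <= {0, 1}
        assert list(occ.columns) == sorted(sim.allele_counts.samples)


def test_gene_model_validation():
    with pytest.raises(ValueError):
        _gene("TTTTAAGGG")  # internal stop
    with pytest.raises(ValueError):
        _gene("TTTGG")  # not divisible by 3
    with pytest.raises(ValueError):
        _gene("TTT")  # too short


def test_gene_model_tsv_fasta_round_trip(tmp_path):
    genes = [_gene("ATGAAATTTGGG", gene_id="gA"), _gene("ATGCCC", gene_id="gB")]
    write_gene_models(genes, tmp_path / "map.tsv", tmp_path / "genes.fa")
    back = read_gene_models(tmp_path / "map.tsv", tmp_path / "genes.fa")
    assert [(g.gene_id, g.seq, g.start, g.end) for g in back] == [
        (g.gene_id, g.seq, g.start, g.end) for g in genes
    ]
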