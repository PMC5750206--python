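"""The diploid genome generator: determinism, calibration, planted truth."""

import json

import numpy as np
import pytest

from haplodyn.config import AgeDistribution, ConfigError, SimulationConfig, SizingError
from haplodyn import synthetic_data as sd


def cfg(**kw):
    base = dict(seed=0, n_contigs=1, contig_length=200_000, n_intact_ltr=10,
                solo_fraction=0.0, n_planted_indels=0)
    base.update(kw)
    return SimulationConfig(**base).validate()


# ---------------------------------------------------------------------------
# ancestral genome


def test_gene_count_matches_density():
    g = sd.generate_ancestral(cfg(contig_length=500_000))
    assert len(g.genes) == 125  # 500 kb at one gene per 4 kb


def test_infeasible_gene_count_raises_sizing_error():
    with pytest.raises(SizingError):
        sd.generate_ancestral(cfg(contig_length=10_000, gene_density=0.01))


def test_determinism_same_seed_same_bytes(tmp_path):
    c = cfg(n_intact_ltr=8, solo_fraction=0.5, n_planted_indels=2,
            indel_size_range=(5000, 8000), contig_length=150_000, n_replicates=1)
    m1 = sd.write_fixture(sd.simulate_genome(c), tmp_path / "a")
    m2 = sd.write_fixture(sd.simulate_genome(c), tmp_path / "b")
    assert m1["files"] == m2["files"]


def test_manifest_checksums_match_files(tmp_path):
    c = cfg(n_intact_ltr=4, n_replicates=1, contig_length=100_000)
    g = sd.simulate_genome(c)
    sd.write_fixture(g, tmp_path)
    import hashlib
    manifest = json.loads((tmp_path / "manifest.json").read_text())
    for name, meta in manifest["files"].items():
        assert hashlib.sha256((tmp_path / name).read_bytes()).hexdigest() == meta["sha256"]


# ---------------------------------------------------------------------------
# LTR planting


def test_zero_age_gives_identical_ltrs():
    c = cfg(ltr_age_distribution=AgeDistribution(kind="uniform", min_age=0.0, max_age=1e-9))
    g = sd.generate_ancestral(c)
    sd.plant_ltr_elements(g, c)
    for el in g.elements:
        seq = g.seqs[el.contig]
        assert seq[el.ltr5[0]:el.ltr5[1]] == seq[el.ltr3[0]:el.ltr3[1]]


def test_tsd_flanks_identical():
    c = cfg(n_intact_ltr=12)
    g = sd.generate_ancestral(c)
    sd.plant_ltr_elements(g, c)
    for el in g.elements:
        seq = g.seqs[el.contig]
        assert seq[el.start - 5:el.start] == seq[el.end:el.end + 5]


def test_divergence_calibration_two_mu_t():
    """200 elements at T = 500 ky: mean LTR-pair divergence within 3 SE of 2 mu T."""
    c = cfg(seed=2, n_contigs=2, contig_length=600_000, n_intact_ltr=200,
            ltr_age_distribution=AgeDistribution(kind="uniform",
                                                 min_age=499_999, max_age=500_001))
    g = sd.generate_ancestral(c)
    sd.plant_ltr_elements(g, c)
    divs, lens = [], []
    for el in g.elements:
        seq = g.seqs[el.contig]
        l5, l3 = seq[el.ltr5[0]:el.ltr5[1]], seq[el.ltr3[0]:el.ltr3[1]]
        divs.append(sum(a != b for a, b in zip(l5, l3)) / len(l5))
        lens.append(len(l5))
    p0 = 1.3e-8 * 5e5
    expect = 2 * p0 * (1 - 2 * p0 / 3)  # pairwise mismatch of two mutated copies
    se = np.sqrt(expect * (1 - expect) / sum(lens))
    assert abs(np.mean(divs) - expect) < 3 * se
    assert np.mean(divs) == pytest.approx(0.013, rel=0.12)


def test_saturating_age_refused():
    with pytest.raises(ConfigError):
        cfg(ltr_age_distribution=AgeDistribution(kind="uniform",
                                                 min_age=0, max_age=6e7)).validate()


# ---------------------------------------------------------------------------
# solo formation


def test_solo_fraction_zero_and_one():
    c0 = cfg(n_intact_ltr=10, solo_fraction=0.0)
    g0 = sd.generate_ancestral(c0)
    sd.plant_ltr_elements(g0, c0)
    sd.form_solo_ltrs(g0, c0)
    assert g0.solos == [] and len(g0.elements) == 10

    c1 = cfg(n_intact_ltr=10, solo_fraction=1.0)
    g1 = sd.generate_ancestral(c1)
    sd.plant_ltr_elements(g1, c1)
    sd.form_solo_ltrs(g1, c1)
    assert len(g1.solos) == 10 and g1.elements == []


def test_solo_length_equals_template_ltr():
    c = cfg(n_intact_ltr=10, solo_fraction=1.0)
    g = sd.generate_ancestral(c)
    sd.plant_ltr_elements(g, c)
    sd.form_solo_ltrs(g, c)
    by_family = {t.name: len(t.ltr) for t in g.library}
    for so in g.solos:
        assert so.end - so.start == by_family[so.family]


# ---------------------------------------------------------------------------
# haplotype derivation


def test_no_snps_no_indels_identical_haplotypes():
    c = cfg(snp_rate=0.0, n_intact_ltr=5)
    g = sd.simulate_genome(c, methylome=False, expression=False)
    assert g.hap_seqs["contig1_A"] == g.hap_seqs["contig1_B"]


def test_realized_identity_within_point_one_of_target():
    c = cfg(seed=3, contig_length=1_000_000, n_intact_ltr=20)
    g = sd.simulate_genome(c, methylome=False, expression=False)
    identity = 100.0 * (1 - g.n_snps / g.snp_eligible_bp)
    assert abs(identity - 98.2) < 0.1


def test_single_indel_length_difference_exact():
    c = cfg(n_intact_ltr=6, n_planted_indels=1, indel_size_range=(10_000, 10_001))
    g = sd.simulate_genome(c, methylome=False, expression=False)
    diff = len(g.hap_seqs["contig1_A"]) - len(g.hap_seqs["contig1_B"])
    assert abs(diff) == 10_000
    t = g.indels[0]
    carrier = g.hap_seqs[f"{t.contig}_{t.carrier}"]
    partner = g.hap_seqs[f"{t.contig}_{'B' if t.carrier == 'A' else 'A'}"]
    assert len(carrier) - len(partner) == 10_000
    # carrier contains the planted segment at the recorded breakpoints
    assert t.end - t.start == t.size == 10_000


def test_indel_composition_targets(small_genome):
    fr = [t.ltr_bp / t.size for t in small_genome.indels]
    assert abs(np.mean(fr) - 0.58) < 0.1
    gf = [t.gene_bp / t.size for t in small_genome.indels]
    assert np.mean(gf) < 0.2


# ---------------------------------------------------------------------------
# methylome


def test_cytosine_context_assignment():
    #        0123456789
    seq = b"ACGCAGCCTA"
    df = sd.cytosine_sites(seq)
    fwd = df[df.strand == "+"].set_index("pos")["context"]
    assert fwd[1] == "CpG"      # C at 1 followed by G
    assert fwd[3] == "CHG"      # C A G
    assert fwd[6] == "CHH"      # C C T
    rev = df[df.strand == "-"].set_index("pos")["context"]
    assert rev[2] == "CpG"      # G at 2 preceded by C


def test_full_methylation_gives_full_counts():
    prof = {"gene_body": {"CpG": 1.0, "CHG": 1.0, "CHH": 1.0},
            "ltr_body": {"CpG": 1.0, "CHG": 1.0, "CHH": 1.0},
            "background": {"CpG": 1.0, "CHG": 1.0, "CHH": 1.0}}
    c = cfg(n_intact_ltr=2, methylation_profile=prof, n_replicates=1,
            contig_length=50_000, coverage_mean=5.0)
    g = sd.simulate_genome(c, expression=False)
    rep = g.methylomes[0]
    assert (rep["count_unmethylated"] == 0).all()


def test_gene_body_level_recovered(meth_genome):
    truth = meth_genome.methylation_truth
    rep = meth_genome.methylomes[0]
    lv = truth["true_level"].to_numpy()
    gene_level = meth_genome.config.methylation_profile["gene_body"]["CpG"]
    mask = (lv == gene_level)
    m = rep.loc[mask, "count_methylated"].to_numpy()
    u = rep.loc[mask, "count_unmethylated"].to_numpy()
    tot = (m + u).sum()
    obs = m.sum() / tot
    se = np.sqrt(gene_level * (1 - gene_level) / tot)
    assert abs(obs - gene_level) < 3 * se + 1e-4


# ---------------------------------------------------------------------------
# expression


def test_expression_normalization_and_design(small_genome):
    e = small_genome.expression
    assert e["tpm"].sum() == pytest.approx(1e6, rel=1e-9)
    ind = e[e.in_indel]["tpm"]
    non = e[~e.in_indel]["tpm"]
    frac = (ind < 0.5).mean()
    se = np.sqrt(0.74 * 0.26 / len(ind))
    assert abs(frac - 0.74) < 3 * se + 0.01
    assert non.median() > ind.median()


# ---------------------------------------------------------------------------
# fixture round-trip


def test_gff_roundtrip_matches_truth(tmp_path, small_genome):
    from haplodyn import io_utils
    sd.write_fixture(small_genome, tmp_path)
    seqs = io_utils.read_fasta(tmp_path / "haplotype_A.fasta")
    seqs.update(io_utils.read_fasta(tmp_path / "haplotype_B.fasta"))
    for c in small_genome.contigs:
        for hap in ("A", "B"):
            h = small_genome.hap_name(c, hap)
            assert seqs[h] == small_genome.hap_seqs[h]
    genes = io_utils.load_gene_models(tmp_path / "genes.gff3", seqs)
    truth = {g.id: (g.contig, g.start, g.end, g.strand) for g in small_genome.genes_hap}
    assert len(genes) == len(truth)
    for g in genes:
        assert truth[g.id] == (g.contig, g.start, g.end, g.strand)
    elements, solos = io_utils.load_ltr_annotation(tmp_path / "ltr.gff3")
    etruth = {e.id: (e.start, e.end, e.ltr5, e.ltr3) for e in small_genome.elements_hap}
    assert len(elements) == len(etruth)
    for el in elements:
        assert etruth[el.id] == (el.start, el.end, el.ltr5, el.ltr3)
    assert len(solos) == len(small_genome.solos_hap)
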