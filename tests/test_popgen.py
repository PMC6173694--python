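"""LD estimation, EM haplotype frequencies and Mendelian checks."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from kirtyper.popgen import (
    CohortGenotypes,
    Individual,
    Pedigree,
    PhenotypeTable2x2,
    SampleGenotype,
    _phase_resolutions,
    em_haplotype_freqs,
    ld_d_statistic,
    ld_from_phenotypes,
    mendelian_check,
    pairwise_ld_matrix,
)
from kirtyper.synth import (
    DEFAULT_HAPLOTYPE_FREQS,
    simulate_cohort,
    simulate_pedigree,
    three_generation_structure,
)


# ---------------------------------------------------------------------------
# Mattiuz-style LD
# ---------------------------------------------------------------------------


def test_half_and_half_table_closed_form():
    r = ld_from_phenotypes(PhenotypeTable2x2(50, 0, 0, 50))
    assert r.p_not_a == pytest.approx(np.sqrt(0.5), abs=1e-5)
    assert r.p_not_b == pytest.approx(0.70711, abs=1e-5)
    assert r.h00 == pytest.approx(0.70711, abs=1e-5)
    assert r.D == pytest.approx(0.20711, abs=1e-5)
    assert r.D_prime == pytest.approx(1.0)
    assert r.p_value < 1e-6


def test_exact_independence_counts_give_zero_d():
    # pA = pB = 0.5 on the haplotype scale: d/N = 0.0625, margins 0.25
    n = 1600
    d = int(0.0625 * n)
    b = c = int(0.25 * n) - d
    a = n - b - c - d
    r = ld_from_phenotypes(PhenotypeTable2x2(a, b, c, d))
    assert r.D == pytest.approx(0.0, abs=1e-12)
    assert r.chi2 == pytest.approx(0.0, abs=1e-12)


def test_everyone_carries_both_margins_collapse():
    r = ld_from_phenotypes(PhenotypeTable2x2(100, 0, 0, 0))
    assert r.h00 == 0.0 and r.p_not_a == 0.0 and r.D == 0.0
    assert np.isnan(r.chi2)  # undefined at degenerate margins


def test_nobody_carries_either_is_degenerate_with_warning():
    with pytest.warns(UserWarning, match="degenerate"):
        r = ld_from_phenotypes(PhenotypeTable2x2(0, 0, 0, 80))
    assert r.degenerate and r.D == 0.0


def test_chi2_matches_pearson_asymptotically():
    """The haplotype-scale chi2 and Pearson's phenotype 2x2 chi2 are
    asymptotically the same test near independence."""
    rng = np.random.default_rng(0)
    pa, pb = 0.45, 0.3
    probs = [pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)]
    for _ in range(20):
        a, b, c, d = rng.multinomial(20000, probs)
        ours = ld_from_phenotypes(PhenotypeTable2x2(a, b, c, d)).chi2
        pearson = chi2_contingency(
            np.array([[a, b], [c, d]]), correction=False
        ).statistic
        assert ours == pytest.approx(pearson, rel=0.05, abs=0.05)


def test_vectorized_d_matches_scalar_route():
    tables = [(50, 10, 20, 20), (5, 5, 5, 5), (100, 0, 0, 50)]
    a, b, c, d = (np.array(x) for x in zip(*tables))
    _, _, _, dvec = ld_d_statistic(a, b, c, d)
    for k, tab in enumerate(tables):
        assert dvec[k] == pytest.approx(ld_from_phenotypes(PhenotypeTable2x2(*tab)).D)


def test_estimator_bias_shrinks_with_sample_size():
    """D-hat is consistent: |bias| decreases over n = 100, 1000, 10000 on
    HWE simulations with known association."""
    h = {("A", "B"): 0.2, ("A", "b"): 0.2, ("a", "B"): 0.1, ("a", "b"): 0.5}
    d_true = h[("a", "b")] - 0.6 * 0.7  # absence-scale D
    probs = np.zeros(4)
    for (x1, y1), (x2, y2) in itertools.product(h, h):
        ap, bp = "A" in (x1, x2), "B" in (y1, y2)
        k = 0 if ap and bp else 1 if ap else 2 if bp else 3
        probs[k] += h[(x1, y1)] * h[(x2, y2)]
    rng = np.random.default_rng(5)
    biases = []
    for n, reps in [(100, 20000), (1000, 120000), (10000, 200000)]:
        cnt = rng.multinomial(n, probs, size=reps)
        _, _, _, dh = ld_d_statistic(cnt[:, 0], cnt[:, 1], cnt[:, 2], cnt[:, 3])
        biases.append(abs(float(np.mean(dh)) - d_true))
    assert biases[0] > biases[1] > biases[2]


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _hom_sample(i, hap):
    dl1 = tuple(a for a in (hap[0], hap[0]) if a is not None)
    return SampleGenotype(f"H{i}", dl1=dl1, dl23=(hap[1], hap[1]), ds2=hap[2])


def test_em_equals_direct_counting_on_homozygous_cohort():
    # 2DS2-negative haplotypes only: the per-sample 2DS2 presence flag can
    # never establish homozygosity (1 vs 2 copies look alike), so exactness
    # of counting is a property of the fully phase-certain case.
    haps = [h for h in DEFAULT_HAPLOTYPE_FREQS if not h[2]][:4]
    counts = [5, 3, 2, 2]
    samples = []
    i = 0
    for hap, k in zip(haps, counts):
        for _ in range(k):
            samples.append(_hom_sample(i, hap))
            i += 1
    hf = em_haplotype_freqs(CohortGenotypes(samples))
    total = 2 * sum(counts)
    for hap, k in zip(haps, counts):
        assert hf.freqs[hap] == pytest.approx(2 * k / total, abs=1e-12)


def test_em_loglik_is_monotone_and_freqs_sum_to_one():
    cohort, _ = simulate_cohort(DEFAULT_HAPLOTYPE_FREQS, 150, seed=3)
    hf = em_haplotype_freqs(cohort)
    assert hf.converged
    assert all(b >= a - 1e-9 for a, b in zip(hf.loglik_trace, hf.loglik_trace[1:]))
    assert sum(hf.freqs.values()) == pytest.approx(1.0, abs=1e-9)
    assert min(hf.freqs.values()) >= 0


def test_single_double_heterozygote_splits_phase_evenly():
    s = SampleGenotype("S1", dl1=("KIR2DL1*001",),
                       dl23=("KIR2DL2*001", "KIR2DL3*001"))
    hf = em_haplotype_freqs(CohortGenotypes([s]))
    vals = sorted(hf.freqs.values())
    assert vals == pytest.approx([0.25, 0.25, 0.25, 0.25])


def test_em_recovers_generating_frequencies():
    """Estimates on one n=500 cohort lie within 3 Monte-Carlo SEs of truth,
    with the SE measured from replicate simulations."""
    reps = []
    for seed in range(8):
        cohort, _ = simulate_cohort(DEFAULT_HAPLOTYPE_FREQS, 500, seed=100 + seed)
        hf = em_haplotype_freqs(cohort)
        reps.append({h: hf.freqs.get(h, 0.0) for h in DEFAULT_HAPLOTYPE_FREQS})
    for h, truth in DEFAULT_HAPLOTYPE_FREQS.items():
        ests = np.array([r[h] for r in reps])
        se = ests.std(ddof=1)
        assert abs(ests[0] - truth) <= 3 * max(se, 1e-3)


def test_incompatible_sample_is_named():
    with pytest.raises(ValueError, match="3 KIR2DL1|more than 2"):
        SampleGenotype("bad", dl1=("a", "b", "c"), dl23=("x", "y"))


# ---------------------------------------------------------------------------
# Pairwise LD matrix
# ---------------------------------------------------------------------------


def test_complete_association_flags_the_right_pair():
    freqs = {
        ("KIR2DL1*003", "KIR2DL3*001", False): 0.5,
        ("KIR2DL1*004", "KIR2DL2*001", True): 0.5,
    }
    cohort, _ = simulate_cohort(freqs, 200, seed=9)
    df = pairwise_ld_matrix(cohort)
    row = df[(df.allele_a == "KIR2DL1*003") & (df.allele_b == "KIR2DL3*001")]
    assert len(row) == 1 and bool(row.significant.iloc[0])
    assert row.D.iloc[0] > 0


def test_independent_loci_mostly_non_significant():
    # product frequencies: two independent biallelic loci
    freqs = {}
    for a, pa in (("KIR2DL1*001", 0.6), ("KIR2DL1*002", 0.4)):
        for b, pb in (("KIR2DL3*001", 0.7), ("KIR2DL3*002", 0.3)):
            freqs[(a, b, False)] = pa * pb
    hits = 0
    trials = 0
    for seed in range(10):
        cohort, _ = simulate_cohort(freqs, 300, seed=30 + seed)
        df = pairwise_ld_matrix(cohort)
        sub = df[(df.locus_a == "KIR2DL1") & (df.locus_b == "KIR2DL3")]
        hits += int(sub.significant.sum())
        trials += len(sub)
    assert hits / trials < 0.2  # Bonferroni keeps independent pairs quiet


def test_monomorphic_pairs_flagged_non_computable():
    freqs = {("KIR2DL1*003", "KIR2DL3*001", False): 1.0}
    cohort, _ = simulate_cohort(freqs, 20, seed=1)
    df = pairwise_ld_matrix(cohort)
    assert not df.computable.any()
    assert df.D.isna().all()


def test_single_sample_cohort_degenerate():
    cohort, _ = simulate_cohort(DEFAULT_HAPLOTYPE_FREQS, 1, seed=2)
    df = pairwise_ld_matrix(cohort)
    assert not df.computable.any()


# ---------------------------------------------------------------------------
# Mendelian checks
# ---------------------------------------------------------------------------


def _trio(child, father, mother):
    return Pedigree(
        "F1",
        [
            Individual("dad", genotype=father),
            Individual("mom", genotype=mother),
            Individual("kid", father_id="dad", mother_id="mom", genotype=child),
        ],
    )


def _geno(sid, dl1, dl23, ds2=False):
    return SampleGenotype(sid, dl1=dl1, dl23=dl23, ds2=ds2)


def test_child_allele_absent_from_both_parents_is_inconsistent():
    ped = _trio(
        _geno("kid", ("KIR2DL1*009",), ("KIR2DL3*001", "KIR2DL3*001")),
        _geno("dad", ("KIR2DL1*001", "KIR2DL1*001"), ("KIR2DL3*001", "KIR2DL3*001")),
        _geno("mom", ("KIR2DL1*002", "KIR2DL1*002"), ("KIR2DL3*001", "KIR2DL3*001")),
    )
    assert mendelian_check(ped).status.tolist() == ["inconsistent"]


def test_child_homozygous_for_single_parent_allele_is_inconsistent():
    ped = _trio(
        _geno("kid", ("KIR2DL1*001", "KIR2DL1*001"), ("KIR2DL3*001", "KIR2DL3*001")),
        _geno("dad", ("KIR2DL1*001", "KIR2DL1*002"), ("KIR2DL3*001", "KIR2DL3*001")),
        _geno("mom", ("KIR2DL1*003", "KIR2DL1*003"), ("KIR2DL3*001", "KIR2DL3*001")),
    )
    assert mendelian_check(ped).status.tolist() == ["inconsistent"]


def test_faithful_simulated_family_fully_consistent():
    for seed in range(5):
        ped, _ = simulate_pedigree(
            DEFAULT_HAPLOTYPE_FREQS, three_generation_structure(), seed=seed
        )
        df = mendelian_check(ped)
        assert (df.status == "consistent").all()


def test_injected_de_novo_is_the_flagged_child():
    ped, truth = simulate_pedigree(
        DEFAULT_HAPLOTYPE_FREQS, three_generation_structure(), seed=21, n_denovo=1
    )
    df = mendelian_check(ped)
    flagged = set(df[df.status == "inconsistent"].individual)
    assert flagged == set(truth["injected_denovo"])


def test_unique_transmission_is_reported():
    ped = _trio(
        _geno("kid", ("KIR2DL1*001",), ("KIR2DL2*001", "KIR2DL3*001")),
        _geno("dad", ("KIR2DL1*001", "KIR2DL1*001"), ("KIR2DL3*001", "KIR2DL3*001")),
        _geno("mom", (), ("KIR2DL2*001", "KIR2DL2*001")),
    )
    df = mendelian_check(ped)
    assert df.status.tolist() == ["consistent"]
    pat, mat = df.transmission.iloc[0]
    assert pat == ("KIR2DL1*001", "KIR2DL3*001")
    assert mat == (None, "KIR2DL2*001")


def test_missing_parent_genotype_skips_child():
    ped = Pedigree(
        "F1",
        [
            Individual("dad"),
            Individual("mom", genotype=_geno("mom", (), ("KIR2DL2*001",) * 2)),
            Individual(
                "kid",
                father_id="dad",
                mother_id="mom",
                genotype=_geno("kid", (), ("KIR2DL2*001",) * 2),
            ),
        ],
    )
    assert mendelian_check(ped).status.tolist() == ["skipped"]


def test_pedigree_cycle_rejected():
    with pytest.raises(ValueError, match="cycle"):
        Pedigree(
            "F1",
            [
                Individual("a", father_id="b"),
                Individual("b", father_id="a"),
            ],
        )


def test_agrees_with_exhaustive_phase_enumeration_oracle():
    """Random trios: verdict must equal a brute-force oracle that tries every
    ordered pair of parental haplotype transmissions directly."""
    rng = np.random.default_rng(77)
    haps = list(DEFAULT_HAPLOTYPE_FREQS)
    for _ in range(60):
        pick = lambda: haps[rng.integers(len(haps))]
        f1, f2, m1, m2 = pick(), pick(), pick(), pick()
        # child either faithful or random (possibly violating)
        if rng.random() < 0.5:
            c1, c2 = f1 if rng.random() < 0.5 else f2, m1 if rng.random() < 0.5 else m2
        else:
            c1, c2 = pick(), pick()

        def to_geno(sid, h1, h2):
            return SampleGenotype(
                sid,
                dl1=tuple(a for a in (h1[0], h2[0]) if a is not None),
                dl23=(h1[1], h2[1]),
                ds2=h1[2] or h2[2],
            )

        ped = _trio(to_geno("kid", c1, c2), to_geno("dad", f1, f2), to_geno("mom", m1, m2))
        got = mendelian_check(ped).status.iloc[0]
        # oracle: enumerate parental transmissions over *unphased* parent
        # genotypes exactly as the checker's contract states
        child = to_geno("kid", c1, c2)
        dadg, momg = to_geno("dad", f1, f2), to_geno("mom", m1, m2)
        ok = False
        for pr in _phase_resolutions(child, with_ds2=False):
            ch = [h[:2] for h in pr]
            for fp in _phase_resolutions(dadg, with_ds2=False):
                for mp in _phase_resolutions(momg, with_ds2=False):
                    fh = {h[:2] for h in fp}
                    mh = {h[:2] for h in mp}
                    if (ch[0] in fh and ch[1] in mh) or (ch[1] in fh and ch[0] in mh):
                        ok = True
        if ok and child.ds2 and not (dadg.ds2 or momg.ds2):
            ok = False
        assert got == ("consistent" if ok else "inconsistent")
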