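import numpy as np
import pytest

from ampliscreen.hiplex_sim import design_tiles, make_cohort_fixture
from ampliscreen.pgeno import (
    GenotypeCall,
    InsertionSite,
    ReadClass,
    genotype_cohort,
    genotype_site,
    read_site_table,
    reverse_complement,
    scan_read,
    write_site_table,
)

LEFT = "CCAAGCACAT"
RIGHT = "CCCACTTGTA"
SITE = InsertionSite("gc_ins", LEFT, "GC", RIGHT)


def mutate(seq, positions, rng=None):
    """Flip the given 0-based positions to a different base."""
    seq = list(seq)
    for p in positions:
        seq[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[p]]
    return "".join(seq)


def oracle_scan(read, site):
    """Brute-force all-offsets Hamming search, independent of scan_read."""

    def hd(a, b):
        return sum(x != y for x, y in zip(a, b))

    L = site.left_flank.upper()
    I = site.inserted.upper()
    R = site.right_flank.upper()
    mm = site.max_mismatch_per_flank

    def one_orientation(s):
        mut = wt = False
        for i in range(len(s) - len(L) + 1):
            if hd(s[i : i + len(L)], L) <= mm:
                j = i + len(L)
                if (
                    s[j : j + len(I)] == I
                    and len(s) >= j + len(I) + len(R)
                    and hd(s[j + len(I) : j + len(I) + len(R)], R) <= mm
                ):
                    mut = True
                if len(s) >= j + len(R) and hd(s[j : j + len(R)], R) <= mm:
                    wt = True
        if mut:
            return ReadClass.MUT
        if wt:
            return ReadClass.WT
        return None

    for oriented in (read.upper(), reverse_complement(read.upper())):
        result = one_orientation(oriented)
        if result is not None:
            return result
    return ReadClass.UNINFORMATIVE


class TestScanRead:
    def test_exact_mutant(self):
        assert scan_read(LEFT + "GC" + RIGHT, SITE) is ReadClass.MUT

    def test_wild_type_with_two_left_mismatches(self):
        read = mutate(LEFT, [0, 5]) + RIGHT
        assert scan_read(read, SITE) is ReadClass.WT

    def test_three_mismatches_uninformative(self):
        read = mutate(LEFT, [0, 4, 8]) + RIGHT
        assert scan_read(read, SITE) is ReadClass.UNINFORMATIVE

    def test_reverse_complement_detected_and_switchable(self):
        read = reverse_complement(LEFT + "GC" + RIGHT)
        assert scan_read(read, SITE) is ReadClass.MUT
        assert scan_read(read, SITE, scan_revcomp=False) is ReadClass.UNINFORMATIVE

    def test_inserted_bases_must_match_exactly(self):
        assert scan_read(LEFT + "GT" + RIGHT, SITE) is ReadClass.UNINFORMATIVE

    def test_non_dna_symbols_count_as_mismatches(self):
        read = LEFT[:-2] + "QN" + RIGHT  # two junk symbols within the left flank
        assert scan_read(read, SITE) is ReadClass.WT

    def test_oracle_equivalence_random_reads(self):
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        for _ in range(1500):
            kind = rng.integers(0, 3)
            if kind == 0:
                read = "".join(bases[rng.integers(0, 4, size=rng.integers(20, 41))])
            else:
                core = LEFT + ("GC" if kind == 1 else "") + RIGHT
                core = mutate(core, rng.choice(len(core), size=rng.integers(0, 5), replace=False))
                pad = "".join(bases[rng.integers(0, 4, size=rng.integers(0, 8))])
                read = (pad + core)[:40]
            if rng.random() < 0.5:
                read = reverse_complement(read)
            assert scan_read(read, SITE) is oracle_scan(read, SITE), read


class TestGenotypeSite:
    def make_reads(self, n_wt, n_mut, n_junk=0):
        return (
            [LEFT + RIGHT] * n_wt
            + [LEFT + "GC" + RIGHT] * n_mut
            + ["ACGT" * 10] * n_junk
        )

    @pytest.mark.parametrize(
        "n_wt,n_mut,expected",
        [
            (100, 0, "SS"),
            (39, 0, "NoCall"),  # below the 40-read floor
            (50, 50, "Sr"),
            (90, 10, "SS"),
            (85, 15, "SS"),  # exactly 15% is not "more than 15%"
            (84, 16, "Sr"),
            (15, 85, "rr"),  # symmetric boundary is inclusive
            (16, 84, "Sr"),
            (0, 100, "rr"),
        ],
    )
    def test_threshold_arithmetic(self, n_wt, n_mut, expected):
        call = genotype_site(self.make_reads(n_wt, n_mut), SITE)
        assert call.call == expected
        assert (call.n_wt, call.n_mut) == (n_wt, n_mut)

    def test_uninformative_reads_never_change_call(self):
        base = genotype_site(self.make_reads(50, 50), SITE)
        noisy = genotype_site(self.make_reads(50, 50, n_junk=500), SITE)
        assert (base.call, base.n_wt, base.n_mut) == (
            noisy.call,
            noisy.n_wt,
            noisy.n_mut,
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        reads = self.make_reads(60, 30, n_junk=10)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        assert genotype_site(reads, SITE).call == genotype_site(shuffled, SITE).call

    def test_empty_read_set_is_nocall_with_zero_counts(self):
        call = genotype_site([], SITE)
        assert (call.call, call.coverage) == ("NoCall", 0)
        assert call.proportion is None

    def test_raising_min_coverage_never_creates_calls(self):
        reads = self.make_reads(30, 30)
        for lo, hi in [(10, 40), (40, 80), (60, 100)]:
            a = genotype_site(reads, SITE, min_coverage=lo)
            b = genotype_site(reads, SITE, min_coverage=hi)
            if a.call == "NoCall":
                assert b.call == "NoCall"

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            genotype_site([], SITE, carrier_min_proportion=0.9, hom_min_proportion=0.5)


class TestGenotypeCohort:
    def test_noiseless_cohort_recovers_truth(self, small_model, small_sites):
        sim = make_cohort_fixture(
            n_samples=12,
            site_freqs={"gc_ins": 0.4},
            sites=small_sites,
            model=small_model,
            mean_depth=200,
            error_rate=0.0,
            seed=21,
        )
        anchor = small_sites["gc_ins"].pos
        seq = small_model.sequence
        site = InsertionSite(
            "gc_ins", seq[anchor - 10 : anchor], "GC", seq[anchor : anchor + 10]
        )
        table, summary = genotype_cohort(
            {s.sample_id: sim.reads[s.sample_id] for s in sim.specs}, site
        )
        truth = sim.truth[sim.truth["site_id"] == "gc_ins"].set_index("sample_id")
        merged = table.set_index("sample_id").join(truth["genotype"])
        assert (merged["call"] == merged["genotype"]).all()
        assert summary["n_NoCall"] == 0

    def test_low_coverage_sample_is_nocall(self):
        samples = {
            "ok": [LEFT + RIGHT] * 100,
            "thin": [LEFT + RIGHT] * 20,
        }
        table, summary = genotype_cohort(samples, SITE)
        assert table.set_index("sample_id").loc["thin", "call"] == "NoCall"
        assert summary["n_NoCall"] == 1

    def test_unreadable_fastq_flagged_not_fatal(self, tmp_path):
        good = tmp_path / "good.fastq"
        good.write_text(f"@r1\n{LEFT + RIGHT}\n+\n{'I' * 20}\n" * 50)
        table, summary = genotype_cohort(
            {"good": good, "missing": tmp_path / "nope.fastq"}, SITE
        )
        flagged = table.set_index("sample_id")
        assert flagged.loc["missing", "error"] != ""
        assert summary["n_error"] == 1
        assert flagged.loc["good", "call"] == "SS"

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            genotype_cohort({}, SITE)


def test_site_table_round_trip(tmp_path):
    path = tmp_path / "sites.tsv"
    write_site_table([SITE], path)
    (loaded,) = read_site_table(path)
    assert loaded == SITE


def test_invalid_site_definitions():
    with pytest.raises(ValueError):
        InsertionSite("x", "", "GC", RIGHT)
    with pytest.raises(ValueError):
        InsertionSite("x", LEFT, "", RIGHT)
    with pytest.raises(ValueError):
        InsertionSite("x", LEFT, "GC", RIGHT, max_mismatch_per_flank=11)
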