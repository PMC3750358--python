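"""Best-hit identification: identity definition, exact prefiltered search, tallies."""
import numpy as np
import pytest

import bulkbarcode as bb
from bulkbarcode.identify import IdentifyParams, best_match


def dp_infix_alignment(read, ref):
    """Independent semi-global DP oracle: minimal edit distance of `read`
    against any infix of `ref`, plus aligned-column count via traceback.

    Returns (distance, matches, columns) for one optimal alignment.
    """
    n, m = len(read), len(ref)
    INF = 10**9
    # dp[i][j]: min distance aligning read[:i] to an infix of ref ending at j
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        dp[i][0] = i
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dp[i - 1][j - 1] + (read[i - 1] != ref[j - 1])
            dele = dp[i][j - 1] + 1  # consume ref
            ins = dp[i - 1][j] + 1  # consume read
            dp[i][j] = min(sub, dele, ins)
    end_j = min(range(m + 1), key=lambda j: dp[n][j])
    dist = dp[n][end_j]
    # traceback for column counts
    i, j = n, end_j
    matches = cols = 0
    while i > 0:
        if j > 0 and dp[i][j] == dp[i - 1][j - 1] + (read[i - 1] != ref[j - 1]):
            matches += read[i - 1] == ref[j - 1]
            cols += 1
            i, j = i - 1, j - 1
        elif j > 0 and dp[i][j] == dp[i][j - 1] + 1:
            cols += 1
            j -= 1
        else:
            cols += 1
            i -= 1
    return dist, matches, cols


def brute_force_best(read, db, gene, params=IdentifyParams()):
    """Argmax of pairwise_identity over all references, spec tie rule."""
    recs = sorted(db.by_gene(gene), key=lambda r: (r.species, r.specimen_id))
    scored = [(bb.pairwise_identity(read, r.sequence), r) for r in recs]
    best = max(s for s, _ in scored)
    leaders = [r for s, r in scored if s == best]
    return leaders[0].species, best


class TestPairwiseIdentity:
    def test_identical(self):
        assert bb.pairwise_identity("A" * 100, "A" * 100) == 1.0

    def test_single_mismatch_quarter(self):
        assert bb.pairwise_identity("ACGT", "ACGA") == 0.75

    def test_read_as_subregion_end_gaps_free(self):
        ref = "GGGG" + "ACGTACGTAC" + "TTTT"
        assert bb.pairwise_identity("ACGTACGTAC", ref) == 1.0

    def test_internal_gap_counts_as_mismatch(self):
        read = "ACGTACGT"
        ref = "ACGTTACGT"  # one extra base: 8 matches over 9 columns
        assert bb.pairwise_identity(read, ref) == pytest.approx(8 / 9)

    def test_n_counts_as_mismatch_even_vs_n(self):
        assert bb.pairwise_identity("ACGN", "ACGN") == 0.75
        assert bb.pairwise_identity("ACGN", "ACGT") == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bb.pairwise_identity("", "ACGT")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = "".join(rng.choice(list("ACGT"), 200))
        # reads: noisy sub-regions of the reference
        start = int(rng.integers(0, 80))
        read = list(ref[start : start + 120])
        for _ in range(int(rng.integers(0, 12))):
            i = int(rng.integers(0, len(read)))
            op = rng.random()
            if op < 0.6:
                read[i] = "ACGT"[int(rng.integers(4))]
            elif op < 0.8:
                read.insert(i, "ACGT"[int(rng.integers(4))])
            else:
                del read[i]
        read = "".join(read)
        dist, matches, cols = dp_infix_alignment(read, ref)
        got = bb.pairwise_identity(read, ref)
        # the minimal distance is unique; among minimal alignments the column
        # count can differ by a column or two, so identity agrees to 2/len
        assert abs(got - matches / cols) <= 2 / len(read)
        from bulkbarcode.identify import _align_counts

        _, _, d_impl = _align_counts(read, ref)
        assert d_impl == dist


@pytest.fixture(scope="module")
def db():
    return bb.simulate_reference_db(n_species=6, n_per_species=3, seed=71)


class TestBestMatch:

    def test_exact_copy_accepted_at_identity_one(self, db):
        rec = db.by_gene("COI")[0]
        a = best_match(rec.sequence, db, "COI")
        assert a.best_species == rec.species
        assert a.identity == 1.0
        assert a.accepted

    def test_below_threshold_reported_not_accepted(self, db):
        rec = db.by_gene("COI")[0]
        rng = np.random.default_rng(72)
        seq = list(rec.sequence)
        positions = rng.choice(len(seq), size=14, replace=False)  # 381/395 = 96.5%
        for i in positions:
            seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
        a = best_match("".join(seq), db, "COI")
        assert a.identity == pytest.approx(1 - 14 / 395)
        assert a.best_species == rec.species
        assert not a.accepted

    def test_strictly_greater_than_threshold(self):
        # identity exactly at the threshold must be rejected (> not >=)
        db = bb.ReferenceDB([bb.SpeciesRecord("a1", "A a", "COI", "ACGT" * 25)])
        read = list("ACGT" * 25)
        for i in (0, 33, 66):
            read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        a = best_match("".join(read), db, "COI", IdentifyParams(min_identity=0.97))
        assert a.identity == 0.97
        assert not a.accepted

    def test_empty_gene_db_errors(self, db):
        with pytest.raises(ValueError):
            best_match("ACGT", bb.ReferenceDB(), "COI")

    @pytest.mark.parametrize("seed", range(5))
    def test_prefilter_equals_brute_force(self, db, seed):
        rng = np.random.default_rng(100 + seed)
        recs = db.by_gene("COI")
        rec = recs[int(rng.integers(len(recs)))]
        seq = list(rec.sequence)
        for _ in range(int(rng.integers(0, 30))):
            i = int(rng.integers(len(seq)))
            seq[i] = "ACGT"[int(rng.integers(4))]
        read = "".join(seq)
        a = best_match(read, db, "COI")
        bf_species, bf_identity = brute_force_best(read, db, "COI")
        assert a.best_species == bf_species
        assert a.identity == bf_identity

    def test_tie_prefers_lexicographic_species_and_flags(self):
        db = bb.ReferenceDB(
            [
                bb.SpeciesRecord("b1", "Beta b", "COI", "ACGTACGTACGTACGTACGT"),
                bb.SpeciesRecord("a1", "Alpha a", "COI", "ACGTACGTACGTACGTACGT"),
            ]
        )
        a = best_match("ACGTACGTACGTACGTACGT", db, "COI")
        assert a.best_species == "Alpha a"
        assert a.tied
        assert a.runner_up == a.identity

    def test_threshold_monotonicity(self, db):
        rng = np.random.default_rng(73)
        reads = []
        for rec in db.by_gene("COI")[:6]:
            seq = list(rec.sequence)
            for _ in range(int(rng.integers(0, 20))):
                i = int(rng.integers(len(seq)))
                seq[i] = "ACGT"[int(rng.integers(4))]
            reads.append("".join(seq))
        accepted = []
        for thr in (0.90, 0.95, 0.97, 0.99):
            params = IdentifyParams(min_identity=thr)
            accepted.append(
                sum(best_match(r, db, "COI", params).accepted for r in reads)
            )
        assert accepted == sorted(accepted, reverse=True)

    def test_per_gene_threshold_override(self, db):
        params = IdentifyParams(min_identity=0.97, per_gene_min_identity={"CytB": 0.90})
        assert params.threshold("COI") == 0.97
        assert params.threshold("CytB") == 0.90


class TestClassifySample:
    def test_counts_and_marginals_match_per_read_assignments(self):
        db = bb.simulate_reference_db(n_species=5, n_per_species=2, seed=74)
        mids = bb.make_mid_scheme(["S1", "S2"], seed=75)
        truth = bb.simulate_community(
            db, {"S1": {"Simulomyia sp.1": 3}, "S2": {"Simulomyia sp.2": 2}}, seed=76
        )
        reads, truth = bb.simulate_reads(truth, bb.SimParams(seed=77, n_runs=1), mids)
        result = bb.demultiplex(reads, mids)
        tagged = [tr for b in result.bins.values() for tr in b if tr.gene != "ambiguous"]
        assignments = bb.identify_reads(tagged, db)
        counts = bb.classify_sample(assignments)
        accepted = assignments[assignments.accepted]
        for _, row in counts[counts.species != "(unassigned)"].iterrows():
            n = (
                (accepted["sample"] == row["sample"])
                & (accepted.best_species == row.species)
                & (accepted.gene == row.gene)
                & (accepted.direction == row.direction)
            ).sum()
            assert n == row.reads
        assert counts.reads.sum() == len(assignments)

    def test_zero_reads_empty_table(self):
        import pandas as pd

        db = bb.simulate_reference_db(n_species=2, n_per_species=1, seed=78)
        counts = bb.classify_sample(bb.identify_reads([], db))
        assert len(counts) == 0

    def test_simple_tally(self):
        import pandas as pd

        assignments = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(10)],
                "sample": ["S1"] * 10,
                "gene": ["COI"] * 10,
                "direction": ["forward"] * 10,
                "best_species": ["A a"] * 10,
                "best_specimen": ["a1"] * 10,
                "identity": [1.0] * 10,
                "accepted": [True] * 10,
                "runner_up": [0.0] * 10,
                "tied": [False] * 10,
            }
        )
        counts = bb.classify_sample(assignments)
        assert len(counts) == 1
        assert counts.iloc[0].reads == 10
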