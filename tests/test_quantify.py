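import numpy as np
import pytest

from txsimeval.annotation import AnnotationSet
from txsimeval.expression import ExpressionProfile
from txsimeval.matching import MatchCandidate, MatchReport
from txsimeval.pool import reverse_complement
from txsimeval.quantify import (
    evaluate,
    quantify_em,
    read_external_estimates,
)


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def pairs_from(seq, n, rng, read_len=75, insert=250):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, len(seq) - insert + 1))
        frag = seq[start:start + insert]
        out.append((frag[:read_len], reverse_complement(frag[-read_len:])))
    return out


class TestEm:
    def test_single_transcript_takes_all(self):
        seq = random_seq(2000, 1)
        rng = np.random.default_rng(2)
        est = quantify_em(pairs_from(seq, 50, rng), {"A": seq})
        assert est.proportions["A"] == pytest.approx(1.0)
        assert est.n_unmapped == 0

    def test_unique_assignment_closed_form(self):
        """Two disjoint equal-length transcripts with 300 and 100 uniquely
        assigned pairs: the multinomial MLE is the count fraction."""
        a, b = random_seq(2000, 3), random_seq(2000, 4)
        rng = np.random.default_rng(5)
        pairs = pairs_from(a, 300, rng) + pairs_from(b, 100, rng)
        est = quantify_em(pairs, {"A": a, "B": b})
        assert est.proportions["A"] == pytest.approx(0.75, abs=1e-9)
        assert est.proportions["B"] == pytest.approx(0.25, abs=1e-9)
        # equal effective lengths: FPKM ratio matches the proportion ratio
        assert est.values["A"] / est.values["B"] == pytest.approx(3.0, rel=1e-6)

    def test_identical_transcripts_share_but_conserve(self):
        seq = random_seq(2000, 6)
        rng = np.random.default_rng(7)
        pairs = pairs_from(seq, 200, rng)
        single = quantify_em(pairs, {"A": seq})
        double = quantify_em(pairs, {"A": seq, "B": seq})
        total = double.proportions["A"] + double.proportions["B"]
        assert total == pytest.approx(1.0)
        assert double.values["A"] + double.values["B"] == pytest.approx(
            single.values["A"], rel=1e-6
        )

    def test_likelihood_monotone_and_proportions_conserved(self):
        # overlapping transcripts force genuinely ambiguous assignments
        base = random_seq(3000, 8)
        seqs = {"A": base[:2000], "B": base[1000:3000], "C": base[500:2500]}
        rng = np.random.default_rng(9)
        pairs = (
            pairs_from(seqs["A"], 120, rng)
            + pairs_from(seqs["B"], 60, rng)
            + pairs_from(seqs["C"], 30, rng)
        )
        est = quantify_em(pairs, seqs)
        lls = np.array(est.log_likelihoods)
        assert len(lls) > 2
        assert np.all(np.diff(lls) >= -1e-9)
        assert sum(est.proportions.values()) == pytest.approx(1.0)

    def test_empty_transcript_set_rejected(self):
        with pytest.raises(ValueError):
            quantify_em([], {})

    def test_unmappable_reads_warn_and_zero(self):
        seq = random_seq(1000, 10)
        other = random_seq(1000, 11)
        rng = np.random.default_rng(12)
        with pytest.warns(UserWarning, match="no read pair mapped"):
            est = quantify_em(pairs_from(other, 5, rng), {"A": seq})
        assert est.values["A"] == 0.0
        assert est.n_unmapped == 5


class TestExternalEstimates:
    def test_full_table_preserved(self, tmp_path):
        path = tmp_path / "est.tsv"
        path.write_text("tx1\t10.5\ntx2\t0\n")
        est = read_external_estimates(str(path), ["tx1", "tx2"])
        assert est.values == {"tx1": 10.5, "tx2": 0.0}
        assert est.source == "external-table"

    def test_extra_ids_dropped_with_warning(self, tmp_path):
        path = tmp_path / "est.tsv"
        path.write_text("tx1\t1\nzzz\t2\nyyy\t3\n")
        with pytest.warns(UserWarning, match="2 table rows"):
            est = read_external_estimates(str(path), ["tx1", "tx2"])
        assert est.values["tx2"] == 0.0

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "est.tsv"
        path.write_text("tx1\t-4\n")
        with pytest.raises(ValueError, match="negative"):
            read_external_estimates(str(path), ["tx1"])

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "est.tsv"
        path.write_text("tx1\t1.0\ntx2\n")
        with pytest.raises(ValueError, match=":2"):
            read_external_estimates(str(path), ["tx1", "tx2"])


def profile_of(values):
    return ExpressionProfile(alpha=1.2, beta=0.001, values=values)


def annotation_of(tp_ids, fp_ids):
    labels = {t: "TP" for t in tp_ids}
    labels.update({t: "FP_s" for t in fp_ids})
    return AnnotationSet(annotated_ids=frozenset(labels), labels=labels)


def estimate_of(values):
    from txsimeval.quantify import ExpressionEstimate

    return ExpressionEstimate(values=values, source="external-table")


class TestEvaluate:
    def test_perfect_estimates_and_silent_fps(self):
        truth = profile_of({"a": 10.0, "b": 20.0, "c": 5.0, "x": 0.0})
        est = estimate_of({"a": 10.0, "b": 20.0, "c": 5.0, "x": 0.0})
        metrics = evaluate(truth, est, annotation_of(["a", "b", "c"], ["x"]))
        assert metrics.corr_tp == pytest.approx(1.0)
        assert metrics.fp_tp_ratio == 0.0

    def test_ratio_of_means(self):
        truth = profile_of({"a": 1.0, "b": 2.0, "c": 3.0})
        est = estimate_of({"a": 10.0, "b": 20.0, "c": 15.0, "f": 3.0, "g": 0.0})
        # mean TP estimate 15, mean FP estimate 1.5 -> ratio 0.1
        metrics = evaluate(truth, est, annotation_of(["a", "b", "c"], ["f", "g"]))
        assert metrics.fp_tp_ratio == pytest.approx(1.5 / 15.0)

    def test_scaled_estimates_keep_correlation_one(self):
        truth = profile_of({"a": 3.0, "b": 30.0, "c": 300.0})
        est = estimate_of({"a": 21.0, "b": 210.0, "c": 2100.0})
        metrics = evaluate(truth, est, annotation_of(["a", "b", "c"], []))
        assert metrics.corr_tp == pytest.approx(1.0)

    def test_matched_pairs_route_ids_through_matching(self):
        truth = profile_of({"t1": 5.0, "t2": 50.0, "t3": 500.0})
        report = MatchReport(
            matched_pairs=(
                MatchCandidate("t1", "c1", 0, 0),
                MatchCandidate("t2", "c2", 0, 0),
                MatchCandidate("t3", "c3", 0, 0),
            ),
            tp_ids=frozenset({"t1", "t2", "t3"}),
            fn_ids=frozenset(),
            fp_ids=frozenset({"c9"}),
        )
        est = estimate_of({"c1": 5.0, "c2": 50.0, "c3": 500.0, "c9": 0.0})
        metrics = evaluate(truth, est, report)
        assert metrics.corr_tp == pytest.approx(1.0)
        assert metrics.fp_tp_ratio == 0.0
        assert metrics.sensitivity == 1.0
        assert metrics.precision == 0.75

    def test_too_few_tp_estimates_is_error(self):
        truth = profile_of({"a": 1.0, "b": 2.0})
        est = estimate_of({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="correlation"):
            evaluate(truth, est, annotation_of(["a", "b"], []))

    def test_zero_estimate_tps_are_excluded_and_counted(self):
        truth = profile_of({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        est = estimate_of({"a": 1.0, "b": 2.0, "c": 3.0, "d": 0.0})
        metrics = evaluate(truth, est, annotation_of(["a", "b", "c", "d"], []))
        assert metrics.n_tp_used == 3
        assert metrics.n_tp_zero_estimate == 1


class TestSignalAbsorption:
    def test_read_supported_fps_absorb_more_than_random_fps(self):
        """An assembly artefact is necessarily supported by reads: it
        stands in for an expressed transcript that failed to match, so
        that transcript's reads have nowhere else to go.  A randomly
        annotated silent transcript attracts no reads and its estimate
        stays at zero."""
        expressed = {f"T{i}": random_seq(2000, 40 + i) for i in range(4)}
        silent = random_seq(2000, 50)
        rng = np.random.default_rng(42)
        pairs = []
        for i, seq in enumerate(expressed.values()):
            pairs += pairs_from(seq, 100 * (i + 1), rng)
        truth = profile_of({t: 50.0 * (i + 1) for i, t in enumerate(expressed)})
        tp_ids = ["T0", "T1", "T2"]

        # reconstruction-style FP: a heavily truncated copy of expressed T3
        # (too short to match it) replaces T3 in the discovered set
        recon = {t: expressed[t] for t in tp_ids}
        recon["FP"] = expressed["T3"][600:1500]
        est_recon = quantify_em(pairs, recon)
        m_recon = evaluate(truth, est_recon, annotation_of(tp_ids, ["FP"]))

        annot = {t: expressed[t] for t in tp_ids}
        annot["FP"] = silent
        est_annot = quantify_em(pairs, annot)
        m_annot = evaluate(truth, est_annot, annotation_of(tp_ids, ["FP"]))

        assert m_annot.fp_tp_ratio == 0.0
        assert m_recon.fp_tp_ratio > m_annot.fp_tp_ratio
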