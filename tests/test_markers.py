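"""Alignment filtering, marker/clade presence, pileup consensus, prevalence tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from miage.markers import (
    CladeCall,
    CladeScheme,
    call_clades,
    clade_prevalence_test,
    clade_richness,
    clade_richness_compare,
    consensus_from_pileup,
    filter_alignments,
    marker_presence,
    read_alignments_tsv,
    read_pileups_tsv,
    write_consensus_fasta,
)
from miage.phases import bh_adjust
from miage.simulate import simulate_marker_alignments


def _rec(identity=99.0, frac=1.0, mapq=42, multi=False, marker="m1", read="r1"):
    return {"read_id": read, "marker_id": marker, "percent_identity": identity,
            "aligned_fraction": frac, "mapq": mapq, "multimapping": multi}


def _frame(recs):
    return pd.DataFrame(recs, columns=["read_id", "marker_id", "percent_identity",
                                       "aligned_fraction", "mapq", "multimapping"])


class TestFilterAlignments:
    @pytest.mark.parametrize("rec, kept", [
        (_rec(identity=94.9), False),
        (_rec(identity=95.0), True),
        (_rec(mapq=19), False),
        (_rec(mapq=20), True),
        (_rec(frac=0.49), False),
        (_rec(frac=0.5), True),
        (_rec(multi=True), False),
        (_rec(), True),
    ])
    def test_boundaries(self, rec, kept):
        out = filter_alignments(_frame([rec]))
        assert len(out) == (1 if kept else 0)

    def test_matches_brute_force_predicates_on_random_records(self):
        rng = np.random.default_rng(17)
        recs = [_rec(identity=float(rng.uniform(80, 100)),
                     frac=float(rng.uniform(0, 1)),
                     mapq=int(rng.integers(0, 60)),
                     multi=bool(rng.random() < 0.2),
                     read=f"r{i}") for i in range(1000)]
        df = _frame(recs)
        out = filter_alignments(df)
        expected = {r["read_id"] for r in recs
                    if (not r["multimapping"] and r["percent_identity"] >= 95
                        and r["aligned_fraction"] >= 0.5 and r["mapq"] >= 20)}
        assert set(out["read_id"]) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        df = _frame([_rec(identity=float(rng.uniform(90, 100)),
                          mapq=int(rng.integers(0, 40)), read=f"r{i}")
                     for i in range(200)])
        once = filter_alignments(df)
        twice = filter_alignments(once)
        pd.testing.assert_frame_equal(once, twice)


class TestMarkerPresence:
    def test_25_read_boundary(self):
        df24 = _frame([_rec(read=f"r{i}") for i in range(24)])
        df25 = _frame([_rec(read=f"r{i}") for i in range(25)])
        assert marker_presence(df24) == {}
        assert marker_presence(df25) == {"m1": 25}

    def test_empty_input(self):
        assert marker_presence(_frame([])) == {}

    def test_invariant_to_record_order(self):
        recs = ([_rec(read=f"a{i}", marker="m1") for i in range(30)]
                + [_rec(read=f"b{i}", marker="m2") for i in range(26)])
        fwd = marker_presence(_frame(recs))
        rev = marker_presence(_frame(recs[::-1]))
        assert fwd == rev

    def test_raising_min_reads_never_adds_markers(self):
        recs = [_rec(read=f"r{i}", marker=f"m{i % 3}") for i in range(90)]
        low = marker_presence(_frame(recs), min_reads=25)
        high = marker_presence(_frame(recs), min_reads=30)
        assert set(high) <= set(low)


class TestCladeCalls:
    def _scheme(self, n_markers=100):
        return CladeScheme({"cladeX": {f"m{i}" for i in range(n_markers)}})

    def test_10_percent_boundary_inclusive(self):
        scheme = self._scheme()
        present10 = {f"m{i}": 30 for i in range(10)}
        present9 = {f"m{i}": 30 for i in range(9)}
        assert call_clades(present10, scheme)[0].present
        assert not call_clades(present9, scheme)[0].present

    def test_unknown_markers_warn_and_are_ignored(self):
        scheme = self._scheme(10)
        with pytest.warns(UserWarning, match="not in the clade scheme"):
            calls = call_clades({"m0": 30, "rogue": 99}, scheme)
        assert calls[0].markers_detected == 1

    def test_raising_min_fraction_never_adds_clades(self):
        scheme = CladeScheme({"a": {f"am{i}" for i in range(10)},
                              "b": {f"bm{i}" for i in range(10)}})
        presence = {f"am{i}": 30 for i in range(3)} | {"bm0": 30}
        loose = {c.clade_id for c in call_clades(presence, scheme, min_fraction=0.10) if c.present}
        strict = {c.clade_id for c in call_clades(presence, scheme, min_fraction=0.25) if c.present}
        assert strict <= loose

    def test_shared_markers_rejected_by_scheme(self):
        with pytest.raises(ValueError, match="shared"):
            CladeScheme({"a": {"m1"}, "b": {"m1"}})
        with pytest.raises(ValueError, match="empty"):
            CladeScheme({"a": set()})


class TestConsensus:
    def _pileup(self, rows):
        return pd.DataFrame(rows, columns=["position", "A", "C", "G", "T"])

    def test_margin_boundary(self):
        # interior position (25) so end masking does not interfere
        pileup = self._pileup([(25, 10, 6, 0, 0), (26, 10, 5, 0, 0)])
        cons = consensus_from_pileup(pileup, marker_length=50)
        assert cons[25] == "N"  # margin 4 < 5
        assert cons[26] == "A"  # margin exactly 5

    def test_coverage_boundary(self):
        pileup = self._pileup([(20, 4, 0, 0, 0), (21, 5, 0, 0, 0)])
        cons = consensus_from_pileup(pileup, marker_length=50)
        assert cons[20] == "N"
        assert cons[21] == "A"

    def test_tied_major_allele_masked(self):
        pileup = self._pileup([(20, 10, 10, 0, 0)])
        assert consensus_from_pileup(pileup, marker_length=50)[20] == "N"

    def test_uniform_coverage_masks_only_ends(self):
        pileup = self._pileup([(i, 20, 0, 0, 0) for i in range(100)])
        cons = consensus_from_pileup(pileup, marker_length=100)
        assert cons == "N" * 10 + "A" * 80 + "N" * 10

    def test_empty_pileup_all_n_with_warning(self):
        with pytest.warns(UserWarning, match="empty pileup"):
            cons = consensus_from_pileup(self._pileup([]), marker_length=30)
        assert cons == "N" * 30

    def test_determinism(self):
        rng = np.random.default_rng(0)
        rows = [(i, int(rng.integers(0, 30)), int(rng.integers(0, 30)),
                 int(rng.integers(0, 30)), int(rng.integers(0, 30))) for i in range(60)]
        a = consensus_from_pileup(self._pileup(rows), marker_length=60)
        b = consensus_from_pileup(self._pileup(rows), marker_length=60)
        assert a == b


class TestEndToEndRecovery:
    def _scheme(self):
        return CladeScheme({f"clade{c}": {f"m{c}{i}" for i in range(8)} for c in "ABCD"},
                           {f"m{c}{i}": 300 for c in "ABCD" for i in range(8)})

    def test_planted_clades_recovered_exactly(self):
        scheme = self._scheme()
        recs, _, truth = simulate_marker_alignments(
            scheme, ["cladeA", "cladeC"], coverage=30, error_rate=0.0, seed=3)
        presence = marker_presence(filter_alignments(recs))
        called = {c.clade_id for c in call_clades(presence, scheme) if c.present}
        assert called == set(truth.planted_clades)

    def test_one_percent_error_does_not_change_calls(self):
        scheme = self._scheme()
        for err in (0.0, 0.01):
            recs, _, truth = simulate_marker_alignments(
                scheme, ["cladeB"], coverage=30, error_rate=err, seed=4)
            presence = marker_presence(filter_alignments(recs))
            called = {c.clade_id for c in call_clades(presence, scheme) if c.present}
            assert called == {"cladeB"}

    def test_consensus_matches_planted_sequence_away_from_ends(self):
        scheme = self._scheme()
        _, pileups, truth = simulate_marker_alignments(
            scheme, ["cladeA"], coverage=30, error_rate=0.0, seed=5)
        marker = sorted(pileups)[0]
        cons = consensus_from_pileup(pileups[marker], marker_length=300)
        assert cons[10:-10] == truth.marker_sequences[marker][10:-10]
        assert set(cons[:10]) == {"N"} and set(cons[-10:]) == {"N"}


def _calls(sample_id, present_clades, all_clades=("a", "b", "c")):
    return [CladeCall(sample_id=sample_id, clade_id=c, markers_detected=10,
                      markers_total=10, present=c in present_clades)
            for c in all_clades]


class TestRichnessAndPrevalence:
    def test_richness_counts_and_bound(self):
        calls = {"s1": _calls("s1", ()), "s2": _calls("s2", ("a", "c"))}
        df = clade_richness(calls)
        r = df.set_index("sample_id")["richness"]
        assert r["s1"] == 0 and r["s2"] == 2
        assert (df["richness"] <= 3).all()

    def test_planted_richness_gradient_significant_across_replicates(self):
        # healthy individuals carry ~3 clades, disease ~1
        from miage.profiles import SampleMetadata
        hits = 0
        n_rep = 20
        clades = tuple("abcde")
        for r in range(n_rep):
            rng = np.random.default_rng(700 + r)
            calls, meta = {}, {}
            for g, (status, lam) in enumerate((("nonCF", 3.0), ("CF", 1.0))):
                for s in range(15):
                    sid = f"g{g}s{s}"
                    k = min(int(rng.poisson(lam)), len(clades))
                    present = tuple(rng.choice(clades, size=k, replace=False))
                    calls[sid] = _calls(sid, present, clades)
                    meta[sid] = SampleMetadata(sample_id=sid, subject_id=sid,
                                               age_months=20.0, disease_status=status)
            df = clade_richness(calls, meta)
            _, _, p = clade_richness_compare(df, seed=r)
            if p < 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_identical_prevalence_gives_p_one(self):
        calls = {f"a{i}": _calls(f"a{i}", ("a",)) for i in range(5)}
        calls |= {f"b{i}": _calls(f"b{i}", ("a",)) for i in range(5)}
        groups = {s: ("CF" if s.startswith("a") else "nonCF") for s in calls}
        out = clade_prevalence_test(calls, groups)
        assert out.set_index("clade_id").loc["a", "p_value"] == pytest.approx(1.0)

    def test_total_separation_matches_hypergeometric_closed_form(self):
        calls = {f"a{i}": _calls(f"a{i}", ("a",)) for i in range(10)}
        calls |= {f"b{i}": _calls(f"b{i}", ()) for i in range(10)}
        groups = {s: ("CF" if s.startswith("a") else "nonCF") for s in calls}
        out = clade_prevalence_test(calls, groups, alternative="greater")
        p = out.set_index("clade_id").loc["a", "p_value"]
        assert p == pytest.approx(1.0 / 184_756, rel=1e-9)
        assert p == pytest.approx(stats.hypergeom.sf(9, 20, 10, 10), rel=1e-9)

    def test_bh_flags_match_direct_adjustment(self):
        rng = np.random.default_rng(9)
        calls, groups = {}, {}
        for i in range(12):
            sid = f"s{i}"
            present = tuple(c for c in "abc" if rng.random() < (0.8 if i < 6 else 0.3))
            calls[sid] = _calls(sid, present)
            groups[sid] = "CF" if i < 6 else "nonCF"
        out = clade_prevalence_test(calls, groups)
        np.testing.assert_allclose(out["q_value"].values,
                                   bh_adjust(out["p_value"].values))

    def test_three_ordered_stages_use_chi_squared(self):
        calls, groups = {}, {}
        for i, stage in enumerate(["developmental"] * 6 + ["transitional"] * 6 + ["stable"] * 6):
            sid = f"s{i}"
            calls[sid] = _calls(sid, ("a",) if i % 2 else ())
            groups[sid] = stage
        out = clade_prevalence_test(calls, groups)
        assert set(out.columns) >= {"clade_id", "p_value", "q_value", "fdr_significant"}

    def test_empty_group_rejected(self):
        calls = {"s1": _calls("s1", ("a",))}
        with pytest.raises(ValueError, match="zero samples"):
            clade_prevalence_test(calls, {})


class TestMarkerIO:
    def test_alignments_and_pileups_round_trip(self, tmp_path):
        scheme = CladeScheme({"cladeA": {"mA0", "mA1"}}, {"mA0": 120, "mA1": 120})
        recs, pileups, _ = simulate_marker_alignments(
            scheme, ["cladeA"], coverage=10, error_rate=0.0, seed=6)
        recs.to_csv(tmp_path / "aln.tsv", sep="\t", index=False)
        back = read_alignments_tsv(tmp_path / "aln.tsv")
        pd.testing.assert_frame_equal(back, recs)
        stacked = pd.concat([df.assign(marker_id=m) for m, df in pileups.items()])
        stacked.to_csv(tmp_path / "pile.tsv", sep="\t", index=False)
        back_p = read_pileups_tsv(tmp_path / "pile.tsv")
        assert set(back_p) == set(pileups)

    def test_consensus_fasta_written(self, tmp_path):
        write_consensus_fasta({"m1": "NNACGTNN"}, tmp_path / "c.fasta")
        text = (tmp_path / "c.fasta").read_text()
        assert text == ">m1\nNNACGTNN\n"
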