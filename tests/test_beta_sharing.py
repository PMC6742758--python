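"""Homology profiles, Bray-Curtis/PCoA/PERMANOVA, sharing attribution,
and the within/between specimen-type permutation test."""

import numpy as np
import pandas as pd
import pytest

from viromeco import simgen
from viromeco.assembly import Contig, ContigSet
from viromeco.beta_sharing import (
    SampleMeta,
    bray_curtis,
    coassembly_components,
    homology_profile,
    pcoa,
    permanova,
    pooled_sequences,
    sharing_matrix,
    subject_membership_spectrum,
    within_between_test,
)
from viromeco.homology import HomologyHit


def _cset(sample, read_counts, viruses=None):
    viruses = viruses or {}
    return ContigSet(
        sample,
        [
            Contig(cid, "ACGT" * 50, n, [], sample, viruses.get(cid))
            for cid, n in sorted(read_counts.items())
        ],
    )


def _hit(q, s, ev=1e-30, cov=1.0, alen=200):
    return HomologyHit(q, s, 1.0, alen, ev, cov, alen)


def _meta(contig_sets, types, subjects=None):
    return {
        s: SampleMeta(s, types[s], (subjects or {}).get(s, f"subj_{s}"))
        for s in contig_sets
    }


class TestProfile:
    def test_clone_samples_give_full_sharing(self):
        cs = {
            "x": _cset("x", {"c1": 5, "c2": 5}),
            "y": _cset("y", {"c1": 5, "c2": 5}),
        }
        hits = [
            _hit("x|c1", "y|c1"), _hit("x|c2", "y|c2"),
            _hit("y|c1", "x|c1"), _hit("y|c2", "x|c2"),
        ]
        prof = homology_profile(cs, hits)
        assert prof.loc["x", "y"] == 1.0
        assert prof.loc["y", "x"] == 1.0
        assert prof.loc["x", "x"] == 1.0

    def test_no_hits_zero_off_diagonal(self):
        cs = {"x": _cset("x", {"c1": 5}), "y": _cset("y", {"c1": 5})}
        prof = homology_profile(cs, [])
        assert prof.loc["x", "y"] == 0.0
        assert prof.loc["x", "x"] == 1.0

    def test_read_weighting(self):
        # only the 30-read contig of x hits y -> cell = 30/40 = 0.75
        cs = {"x": _cset("x", {"a": 10, "b": 30}), "y": _cset("y", {"c": 7})}
        prof = homology_profile(cs, [_hit("x|b", "y|c")])
        assert prof.loc["x", "y"] == pytest.approx(0.75)
        assert prof.loc["y", "x"] == 0.0

    def test_pooled_id_convention(self):
        cs = {"x": _cset("x", {"c1": 1})}
        assert list(pooled_sequences(cs)) == ["x|c1"]


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        prof = pd.DataFrame([[1.0, 0.5], [1.0, 0.5]], index=["a", "b"])
        assert bray_curtis(prof).loc["a", "b"] == 0.0

    def test_disjoint_support_one(self):
        prof = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert bray_curtis(prof).loc["a", "b"] == 1.0

    def test_hand_example(self):
        prof = pd.DataFrame([[2.0, 1.0], [1.0, 1.0]], index=["a", "b"])
        assert bray_curtis(prof).loc["a", "b"] == pytest.approx(0.2)

    def test_metric_basics_on_random_profiles(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.uniform(0, 1, (6, 6)))
        d = bray_curtis(prof).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 1)).all()


class TestPCoA:
    def test_collinear_three_points(self):
        d = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc"),
            dtype=float,
        )
        res = pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(2.0)
        axis = res.coordinates["PC1"].to_numpy()
        assert np.allclose(np.sort(axis), [-1.0, 0.0, 1.0], atol=1e-9)
        assert np.all(res.eigenvalues[1:] < 1e-9)

    def test_zero_distances_no_axes(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        res = pcoa(d)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(pd.DataFrame(d))
        coords = res.coordinates.to_numpy()
        back = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(back, d, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            pcoa(d)


def _brute_force_permanova(d, labels):
    """Independent direct-sum oracle for the pseudo-F and R^2."""
    d = np.asarray(d, dtype=float)
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        members = [i for i, l in enumerate(labels) if l == g]
        ss_g = sum(
            d[i, j] ** 2
            for ii, i in enumerate(members)
            for j in members[ii + 1 :]
        )
        ss_within += ss_g / len(members)
    ss_between = ss_total - ss_within
    a = len(groups)
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


class TestPermanova:
    def test_two_point_masses_give_r2_one(self):
        # two groups collapsed onto two distinct points: R2 = 1 and the
        # only permutations tying the infinite pseudo-F are those that
        # exactly re-create the partition -- count them with the same
        # seeded stream to predict p exactly
        n = 20
        d = np.ones((n, n))
        d[: n // 2, : n // 2] = 0.0
        d[n // 2 :, n // 2 :] = 0.0
        np.fill_diagonal(d, 0.0)
        dm = pd.DataFrame(d)
        labels = ["a"] * (n // 2) + ["b"] * (n // 2)
        res = permanova(dm, labels, n_permutations=199, seed=0)
        assert res.R2 == pytest.approx(1.0)
        codes = np.array([0] * (n // 2) + [1] * (n // 2))
        rng = np.random.default_rng(0)
        ties = sum(
            len(set(np.nonzero(rng.permutation(codes) == 0)[0]) ^ set(range(10)))
            in (0, 20)
            for _ in range(199)
        )
        assert res.p == pytest.approx((1 + ties) / 200)
        assert res.p <= 3 / 200

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(6, 12))
            pts = rng.normal(size=(n, 2))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = rng.choice(["a", "b", "c"], size=n).tolist()
            if len(set(labels)) < 2:
                continue
            res = permanova(pd.DataFrame(d), labels, n_permutations=9, seed=1)
            f, r2 = _brute_force_permanova(d, labels)
            assert res.F == pytest.approx(f, rel=1e-10)
            assert res.R2 == pytest.approx(r2, rel=1e-10)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a", "a", "b", "b", "a", "b", "a", "b"]
        res1 = permanova(pd.DataFrame(d), labels, n_permutations=99, seed=4)
        perm = rng.permutation(8)
        res2 = permanova(
            pd.DataFrame(d[np.ix_(perm, perm)]),
            [labels[i] for i in perm],
            n_permutations=99,
            seed=4,
        )
        assert res1.F == pytest.approx(res2.F, rel=1e-10)
        assert res1.R2 == pytest.approx(res2.R2, rel=1e-10)

    def test_agrees_with_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(pd.DataFrame(d), labels, n_permutations=99, seed=6)
        theirs = skbio_permanova(
            skbio.DistanceMatrix(d, [str(i) for i in range(10)]),
            grouping=labels,
            permutations=99,
        )
        assert ours.F == pytest.approx(theirs["test statistic"], rel=1e-8)

    def test_empty_group_impossible_and_guards(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "a"])
        with pytest.raises(ValueError):
            permanova(d, ["a", "b"])


class TestSharingAttribution:
    def test_no_cross_edges_single_sample_components(self):
        cs = {"x": _cset("x", {"c1": 1, "c2": 1}), "y": _cset("y", {"c1": 1})}
        comps = coassembly_components(cs, [], _meta(cs, {"x": "csf", "y": "milk"}))
        assert len(comps) == 3
        assert all(len(c.types_present) == 1 for c in comps)

    def test_transitive_chain_unites_types(self):
        cs = {
            "x": _cset("x", {"c": 1}),
            "y": _cset("y", {"c": 1}),
            "z": _cset("z", {"c": 1}),
        }
        hits = [_hit("x|c", "y|c"), _hit("y|c", "z|c")]
        meta = _meta(cs, {"x": "A", "y": "B", "z": "C"})
        comps = coassembly_components(cs, hits, meta)
        assert len(comps) == 1
        assert comps[0].types_present == {"A", "B", "C"}

    def test_planted_virus_types_recovered(self, small_panel):
        plan = [
            simgen.SampleSpec("csf_1", "csf", "low", "S1"),
            simgen.SampleSpec("plasma_1", "plasma", "low", "S2"),
            simgen.SampleSpec("milk_1", "milk", "low", "S3"),
            simgen.SampleSpec("feces_1", "feces", "high", "S4"),
        ]
        design = simgen.generate_communities(
            small_panel, plan, n_viruses_high=6, n_viruses_low=3,
            within_sharing=1.0, between_sharing=0.0, seed=7,
        )
        csets, _ = simgen.fragment_to_contigs(design, small_panel, fragmentation=1, seed=8)
        hits = simgen.truth_hits(csets)
        meta = {s.sample_id: SampleMeta(s.sample_id, s.specimen_type, s.subject_id)
                for s in design}
        comps = coassembly_components(csets, hits, meta)
        low_types = {"csf", "plasma", "milk"}
        shared_low = [c for c in comps if c.types_present == low_types]
        # low-cluster core viruses are planted in all three low samples
        assert len(shared_low) == 3
        assert not any("feces" in c.types_present and len(c.types_present) > 1
                       for c in comps)

    def test_sharing_matrix_counts(self):
        cs = {"a": _cset("a", {"c": 1}), "b": _cset("b", {"c": 1}),
              "c2": _cset("c2", {"c": 1})}
        meta = _meta(cs, {"a": "CSF", "b": "milk", "c2": "milk"})
        comps = coassembly_components(
            cs, [_hit("a|c", "b|c")], meta
        )  # components: {CSF, milk}, {milk}
        m = sharing_matrix(comps)
        assert m.loc["CSF", "milk"] == pytest.approx(100.0)
        assert m.loc["milk", "CSF"] == pytest.approx(50.0)
        assert m.loc["CSF", "CSF"] == 100.0

    def test_sharing_matrix_half_example(self):
        cs = {"a": _cset("a", {"c": 1, "d": 1}), "b": _cset("b", {"c": 1, "d": 1})}
        meta = _meta(cs, {"a": "CSF", "b": "milk"})
        comps = coassembly_components(cs, [_hit("a|c", "b|c")], meta)
        # components: {CSF+milk}, {CSF}, {milk}
        m = sharing_matrix(comps)
        assert m.loc["CSF", "milk"] == pytest.approx(50.0)
        assert m.loc["milk", "CSF"] == pytest.approx(50.0)

    def test_subject_spectrum(self):
        cs = {f"s{i}": _cset(f"s{i}", {"c": 1}) for i in range(3)}
        meta = _meta(cs, {f"s{i}": "t" for i in range(3)},
                     {f"s{i}": f"P{i}" for i in range(3)})
        hits = [_hit("s0|c", "s1|c"), _hit("s1|c", "s2|c")]
        comps = coassembly_components(cs, hits, meta)
        hist, universal = subject_membership_spectrum(comps, 3)
        assert hist == {3: 1}
        assert universal == 1.0

    def test_subject_spectrum_counting_example(self):
        from viromeco.beta_sharing import SharingComponent

        comps = [
            SharingComponent("a", [("x|c", "x")], {"t"}, {"P1"}),
            SharingComponent("b", [("x|d", "x"), ("y|d", "y")], {"t"}, {"P1", "P2"}),
            SharingComponent(
                "c", [("x|e", "x"), ("y|e", "y"), ("z|e", "z")], {"t"},
                {"P1", "P2", "P3"},
            ),
        ]
        hist, universal = subject_membership_spectrum(comps, 3)
        assert hist == {1: 1, 2: 1, 3: 1}
        assert universal == pytest.approx(1 / 3)


class TestWithinBetween:
    def _clone_design(self):
        """Same-type samples are clones; nothing is shared across types."""
        cs = {}
        hits = []
        for t, viruses in (("A", ["v1", "v2", "v3"]), ("B", ["u1", "u2", "u3"])):
            for k in (1, 2):
                sid = f"{t}{k}"
                cs[sid] = _cset(sid, {f"c{i}": 5 + i for i in range(3)},
                                viruses={f"c{i}": viruses[i] for i in range(3)})
        hits = simgen.truth_hits(cs, include_within_sample=False)
        meta = _meta(cs, {"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        return cs, hits, meta

    def test_planted_separation_gives_minimal_p(self):
        cs, hits, meta = self._clone_design()
        res = within_between_test(cs, hits, meta, n_iterations=1000,
                                  contigs_per_draw=10, seed=0)
        for r in res.values():
            assert r.observed_within == pytest.approx(1.0)
            assert r.observed_between == 0.0
            assert r.p == pytest.approx(1 / 1001)

    def test_zero_iterations_rejected(self):
        cs, hits, meta = self._clone_design()
        with pytest.raises(ValueError):
            within_between_test(cs, hits, meta, n_iterations=0)

    def test_single_sample_type_rejected(self):
        cs = {"a": _cset("a", {"c": 1}), "b": _cset("b", {"c": 1})}
        meta = _meta(cs, {"a": "t1", "b": "t2"})
        with pytest.raises(ValueError, match="at least two"):
            within_between_test(cs, [], meta, n_iterations=10)

    def test_iid_pool_p_roughly_uniform(self):
        # no type signal: p-values should be approximately uniform
        rng = np.random.default_rng(42)
        ps = []
        for run in range(60):
            cs, types = {}, {}
            for si in range(6):
                sid = f"s{si}"
                viruses = rng.choice(40, size=12, replace=False)
                cs[sid] = _cset(
                    sid,
                    {f"c{i}": int(rng.integers(1, 100)) for i in range(12)},
                    viruses={f"c{i}": f"v{viruses[i]}" for i in range(12)},
                )
                types[sid] = "A" if si < 3 else "B"
            hits = simgen.truth_hits(cs, include_within_sample=False)
            res = within_between_test(
                cs, hits, _meta(cs, types), n_iterations=99,
                contigs_per_draw=12, seed=int(rng.integers(2**31)),
            )
            ps.append(res["A"].p)
        ps = np.array(ps)
        assert 0.25 < ps.mean() < 0.75
        assert (ps < 0.2).mean() < 0.45
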