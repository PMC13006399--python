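import numpy as np
import pandas as pd
import pytest

from dtmr.grs import (InstrumentSet, NoInstrumentsError, SelectionRule, apply_action_sign,
                      attach_strength, compute_grs, instrument_strength, ld_clump,
                      orient_to_lowering, pairwise_r2, select_instruments)
from dtmr.gwas_io import TargetGeneRegion

from conftest import make_panel, make_record


def make_instruments(weights, eafs=None, ses=None, source="gwas", pos=None, ea="A", oa="G"):
    k = len(weights)
    eafs = eafs if eafs is not None else [0.3] * k
    ses = ses if ses is not None else [0.02] * k
    pos = pos if pos is not None else [1 + 10_000 * j for j in range(k)]
    table = pd.DataFrame({
        "variant_id": [f"rs{j + 1}" for j in range(k)],
        "chrom": "1",
        "pos": pos,
        "ea": ea,
        "oa": oa,
        "eaf": eafs,
        "weight": weights,
        "se": ses,
        "p": [1e-9] * k,
    })
    return InstrumentSet(variants=table, selection_rule=SelectionRule(source=source))


def _cand(ids, ps, pos=None):
    return pd.DataFrame({
        "variant_id": ids, "chrom": "1",
        "pos": pos if pos is not None else range(len(ids)), "p": ps,
    })


class TestLdClump:
    def test_perfectly_correlated_keeps_lowest_p(self):
        ld = {("a", "b"): 1.0}
        got = ld_clump(_cand(["a", "b"], [1e-9, 1e-8]), ld, r2_max=0.1)
        assert got == ["a"]

    def test_independent_all_retained(self):
        got = ld_clump(_cand(["a", "b", "c"], [1e-9, 1e-8, 1e-7]), {}, r2_max=0.1)
        assert got == ["a", "b", "c"]

    def test_tie_broken_by_position(self):
        cand = _cand(["b", "a"], [1e-8, 1e-8], pos=[200, 100])
        got = ld_clump(cand, {("a", "b"): 0.5}, r2_max=0.1)
        assert got == ["a"]  # same p; earlier position indexes first

    def test_four_blocks_matches_greedy_oracle(self, rng):
        # [DERIVED] brute-force re-run of the stated greedy rule
        n_var = 20
        block = np.repeat(np.arange(4), 5)
        ids = [f"v{j}" for j in range(n_var)]
        ps = rng.uniform(1e-12, 1e-6, size=n_var)
        pos = np.arange(n_var) * 1000
        r2 = {}
        for i in range(n_var):
            for j in range(i + 1, n_var):
                r2[(ids[i], ids[j])] = 0.9 if block[i] == block[j] else float(rng.uniform(0, 0.05))
        cand = _cand(ids, ps, pos=pos)
        got = ld_clump(cand, r2, r2_max=0.1)

        def lookup(a, b):
            return r2.get((a, b), r2.get((b, a), 0.0))

        order = sorted(range(n_var), key=lambda i: (ps[i], "1", pos[i]))
        alive = set(ids)
        expected = []
        for i in order:
            if ids[i] not in alive:
                continue
            expected.append(ids[i])
            alive.discard(ids[i])
            for other in list(alive):
                if lookup(ids[i], other) >= 0.1:
                    alive.discard(other)
        assert got == expected
        assert len(got) == 4  # one index per block


class TestSelectInstruments:
    region = TargetGeneRegion("G1", "1", 40_000, 60_000, "d", "inhibitor")

    def _stats(self):
        recs = []
        for j in range(50):
            recs.append(make_record(
                variant_id=f"rs{j + 1}", pos=1 + 10_000 * j,
                p=1e-9 if j < 12 else 1e-3, eaf=0.3))
        return recs

    def test_fixture_count_matches_manual_filter(self):
        # window [start-100k, end+100k] = [1, 160000] covers rs1..rs16 (pos 1..150001);
        # of those, rs1..rs12 have p < 5e-8; no LD -> k = 12
        stats = self._stats()
        inst = select_instruments(stats, self.region, SelectionRule(), ld={})
        assert inst.k == 12

    def test_maf_exactly_at_threshold_excluded(self):
        stats = [make_record(eaf=0.005)]
        with pytest.raises(NoInstrumentsError, match="MAF"):
            select_instruments(stats, None, SelectionRule(), ld={})

    def test_all_p_above_threshold(self):
        stats = [make_record(variant_id=f"rs{j}", pos=j * 100 + 1, p=1e-7) for j in range(5)]
        with pytest.raises(NoInstrumentsError, match="p-value"):
            select_instruments(stats, None, SelectionRule(), ld={})

    def test_empty_region(self):
        stats = [make_record(chrom="9")]
        with pytest.raises(NoInstrumentsError, match="region"):
            select_instruments(stats, self.region, SelectionRule(), ld={})


class TestOrientation:
    def test_positive_beta_flipped(self):
        inst = orient_to_lowering(make_instruments([0.3], eafs=[0.2]))
        row = inst.variants.iloc[0]
        assert row.weight == pytest.approx(-0.3)
        assert (row.ea, row.oa) == ("G", "A")
        assert row.eaf == pytest.approx(0.8)
        assert inst.orientation == "lowering"

    def test_already_negative_unchanged(self):
        base = make_instruments([-0.3, -0.1])
        inst = orient_to_lowering(base)
        pd.testing.assert_frame_equal(inst.variants, base.variants)

    def test_idempotent(self):
        once = orient_to_lowering(make_instruments([0.3, -0.2]))
        twice = orient_to_lowering(once)
        pd.testing.assert_frame_equal(once.variants, twice.variants)

    def test_zero_weight_dropped(self):
        inst = orient_to_lowering(make_instruments([0.0, -0.2]))
        assert inst.k == 1


class TestActionSign:
    def test_inhibitor_negates(self):
        inst = make_instruments([0.2, -0.1], source="pqtl")
        out = apply_action_sign(inst, "inhibitor")
        assert list(out.variants["weight"]) == pytest.approx([-0.2, 0.1])

    def test_activator_identity(self):
        inst = make_instruments([0.2, -0.1], source="pqtl")
        out = apply_action_sign(inst, "activator")
        assert list(out.variants["weight"]) == pytest.approx([0.2, -0.1])

    def test_inhibitor_involution(self):
        inst = make_instruments([0.2, -0.1], source="pqtl")
        out = apply_action_sign(apply_action_sign(inst, "inhibitor"), "inhibitor")
        assert list(out.variants["weight"]) == pytest.approx([0.2, -0.1])

    def test_gwas_source_rejected(self):
        with pytest.raises(ValueError):
            apply_action_sign(make_instruments([0.2]), "inhibitor")

    def test_unknown_action(self):
        with pytest.raises(ValueError):
            apply_action_sign(make_instruments([0.2], source="pqtl"), "modulator")


class TestComputeGrs:
    def test_all_zero_weights(self, rng):
        d = rng.binomial(2, 0.3, size=(10, 2)).astype(float)
        vec = compute_grs(make_panel(d), make_instruments([0.0, 0.0]))
        assert np.allclose(vec.raw, 0.0)

    def test_single_variant_identity(self):
        d = np.array([[0.0], [1.0], [2.0]])
        vec = compute_grs(make_panel(d), make_instruments([1.0]))
        assert vec.raw == pytest.approx([0.0, 1.0, 2.0])

    def test_matrix_vector_product_fixture(self):
        # [DERIVED] hand arithmetic: raw_i = sum_j d_ij * w_j
        d = np.array([
            [0, 1, 2],
            [2, 2, 0],
            [1, 0, 1],
            [0, 0, 0],
        ], dtype=float)
        w = [0.5, -1.0, 0.25]
        vec = compute_grs(make_panel(d), make_instruments(w))
        assert vec.raw == pytest.approx([-0.5, -1.0, 0.75, 0.0])

    def test_missing_variant_error(self, rng):
        d = rng.binomial(2, 0.3, size=(5, 1)).astype(float)
        with pytest.raises(KeyError, match="rs2"):
            compute_grs(make_panel(d), make_instruments([0.1, 0.2]))

    def test_missing_dosage_mean_imputed(self):
        d = np.array([[0.0], [2.0], [np.nan], [2.0]])
        vec = compute_grs(make_panel(d, mafs=[0.5]), make_instruments([1.0]))
        assert vec.raw[2] == pytest.approx(np.nanmean([0, 2, 2]))

    def test_allele_swap_weight_negation_invariance(self, rng):
        # standardized score unchanged under swap+negate of one variant
        d = rng.binomial(2, 0.4, size=(50, 2)).astype(float)
        panel = make_panel(d)
        a = make_instruments([0.5, -0.3])
        b = make_instruments([0.5, -0.3])
        b.variants.loc[1, ["ea", "oa"]] = ["G", "A"]
        b.variants.loc[1, "eaf"] = 1 - b.variants.loc[1, "eaf"]
        b.variants.loc[1, "weight"] = 0.3
        va, vb = compute_grs(panel, a), compute_grs(panel, b)
        assert va.standardized == pytest.approx(vb.standardized, abs=1e-10)

    def test_standardized_moments(self, rng):
        d = rng.binomial(2, 0.3, size=(200, 3)).astype(float)
        vec = compute_grs(make_panel(d), make_instruments([0.4, -0.2, 0.1]))
        assert abs(vec.standardized.mean()) < 1e-8
        assert abs(vec.standardized.std() - 1) < 1e-8


class TestInstrumentStrength:
    def test_single_variant_formula(self):
        # [DERIVED] R2 = 0.1^2 * 2 * 0.5 * 0.5 = 0.005
        inst = make_instruments([0.1], eafs=[0.5])
        r2, _ = instrument_strength(inst, 2111)
        assert r2 == pytest.approx(0.005)

    def test_f_statistic_formula(self):
        # [DERIVED] F = (2111 - 1 - 1)/1 * 0.005/0.995 = 10.598...
        inst = make_instruments([0.1], eafs=[0.5])
        _, f = instrument_strength(inst, 2111)
        assert f == pytest.approx(2109 * 0.005 / 0.995, rel=1e-12)
        assert f == pytest.approx(10.60, abs=0.01)

    def test_zero_weights(self):
        r2, f = instrument_strength(make_instruments([0.0, 0.0]), 1000)
        assert r2 == 0.0 and f == 0.0

    def test_monotone_in_added_variant(self):
        r2_small, _ = instrument_strength(make_instruments([0.1]), 1000)
        r2_big, _ = instrument_strength(make_instruments([0.1, 0.05]), 1000)
        assert r2_big > r2_small

    def test_maf_missing_fallback(self):
        inst = make_instruments([0.1, 0.2], ses=[0.02, 0.05])
        inst.variants.loc[0, "eaf"] = np.nan
        r2, f = instrument_strength(inst, 1000)
        assert np.isnan(r2)
        assert f == pytest.approx(np.mean([(0.1 / 0.02) ** 2, (0.2 / 0.05) ** 2]))

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            instrument_strength(make_instruments([0.1, 0.2]), 3)

    def test_attach_strength(self):
        inst = attach_strength(make_instruments([0.1], eafs=[0.5]), 2111)
        assert inst.r_squared == pytest.approx(0.005)


class TestPairwiseR2:
    def test_duplicate_columns_r2_one(self, rng):
        d = rng.binomial(2, 0.5, size=(100, 1)).astype(float)
        panel = make_panel(np.hstack([d, d]))
        r2 = pairwise_r2(panel)
        assert r2.loc["rs1", "rs2"] == pytest.approx(1.0)
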