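"""Metric definitions (molecule-first averaging), the three loss terms, and
their gradients against central finite differences."""

import numpy as np
import pytest

from tsgeo.autodiff import Tensor
from tsgeo.losses import (edm_penalty, edm_penalty_value, loss_l1, loss_l2,
                          loss_l3, total_loss)
from tsgeo.metrics import molecular_mae, molecular_mape, stratified_errors
from tsgeo.model import ModelConfig, PSIModel
from tsgeo.structures import BondChange, classify_pairs, strict_pairs
from tsgeo.synthetic import SyntheticConfig, generate

from conftest import randomize_heads


class TestMolecularMetrics:
    def test_identity_is_zero(self):
        d = [np.array([100.0, 150.0]), np.array([120.0])]
        assert molecular_mae(d, d) == 0.0
        assert molecular_mape(d, d) == 0.0

    def test_single_pair_values(self):
        assert molecular_mae([np.array([110.0])], [np.array([100.0])]) == 10.0
        assert molecular_mape([np.array([190.0])], [np.array([200.0])]) == \
            pytest.approx(5.0)

    def test_molecule_first_averaging(self):
        # reaction A: per-pair APEs 10% and 10% -> 10%; reaction B exact -> 0%
        pred = [np.array([110.0, 220.0]), np.array([50.0, 60.0, 70.0])]
        true = [np.array([100.0, 200.0]), np.array([50.0, 60.0, 70.0])]
        assert molecular_mape(pred, true) == pytest.approx(5.0)
        # MAE: reaction means 15 pm and 0 pm -> 7.5 pm
        assert molecular_mae(pred, true) == pytest.approx(7.5)

    def test_reactions_weigh_equally_regardless_of_size(self):
        big_exact = np.full(45, 100.0)
        pred = [np.array([110.0]), big_exact]
        true = [np.array([100.0]), big_exact]
        assert molecular_mae(pred, true) == pytest.approx(5.0)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            molecular_mae([np.zeros(3)], [np.zeros(4)])

    def test_zero_true_distance_rejected(self):
        with pytest.raises(ValueError):
            molecular_mape([np.array([1.0])], [np.array([0.0])])


class TestStratifiedErrors:
    def test_exact_predictions_zero_everywhere(self, small_dataset):
        true = [
            r.ts_ref.strict_pair_distances(strict_pairs(r.n_atoms)) * 100
            for r in small_dataset
        ]
        cats = [classify_pairs(r) for r in small_dataset]
        rep = stratified_errors(true, true, cats)
        assert rep.molecular_mape_pct == 0.0
        assert all(v == 0.0 for v in rep.per_category_ape_pct.values())
        assert sum(rep.category_counts.values()) == sum(len(t) for t in true)

    def test_pooled_ape_is_count_weighted_category_mean(self):
        rng = np.random.default_rng(0)
        true = [rng.uniform(100, 300, size=6) for _ in range(3)]
        pred = [t * rng.uniform(0.9, 1.1, size=6) for t in true]
        cats = [[BondChange.NONE_NONE, BondChange.FORMATION, BondChange.BREAKAGE,
                 BondChange.BOND_BOND, BondChange.NONE_NONE, BondChange.BOND_BOND]
                for _ in range(3)]
        rep = stratified_errors(pred, true, cats)
        pooled = np.mean(np.concatenate(
            [np.abs(t - p) / t * 100 for p, t in zip(pred, true)]))
        weighted = sum(rep.per_category_ape_pct[c] * rep.category_counts[c]
                       for c in rep.per_category_ape_pct) / \
            sum(rep.category_counts.values())
        assert weighted == pytest.approx(pooled)

    def test_no_bond_change_means_no_formation_or_breakage(self):
        data = generate(SyntheticConfig(n_reactions=4, p_bond_change=0.0,
                                        stretch_range=(0.99, 1.01),
                                        noise=0.0, seed=3))
        for r in data:
            cats = classify_pairs(r)
            assert BondChange.FORMATION not in cats
            assert BondChange.BREAKAGE not in cats


class TestLossL1:
    def _outputs(self, model, reactions):
        return model.forward_batch(reactions)

    def test_exact_ratios_give_zero(self, small_dataset, tiny_configs):
        mcfg, fcfg = tiny_configs
        model = PSIModel(mcfg, fcfg)
        outs = self._outputs(model, small_dataset[:2])
        for out, rxn in zip(outs, small_dataset[:2]):
            d_true = rxn.ts_ref.strict_pair_distances(out.pair_index)
            out.ratios = Tensor(d_true / out.d_interp)
        assert float(loss_l1(outs, small_dataset[:2]).data) == pytest.approx(0.0)

    def test_unit_ratios_reproduce_interpolation_error(self, small_dataset,
                                                       tiny_configs):
        mcfg, fcfg = tiny_configs
        model = PSIModel(mcfg, fcfg)  # zero heads: ratios == 1
        rxns = small_dataset[:3]
        outs = self._outputs(model, rxns)
        l1 = float(loss_l1(outs, rxns).data)
        per_rxn = []
        for out, rxn in zip(outs, rxns):
            d_true = rxn.ts_ref.strict_pair_distances(out.pair_index)
            per_rxn.append(np.mean(np.abs(out.d_interp - d_true)))
        assert l1 == pytest.approx(np.mean(per_rxn))

    def test_missing_reference_ts_rejected(self, small_dataset, tiny_configs):
        mcfg, fcfg = tiny_configs
        model = PSIModel(mcfg, fcfg)
        r = small_dataset[0]
        from tsgeo.structures import Reaction

        bare = Reaction(r.reactant, r.product, reaction_id="no-ts")
        with pytest.raises(ValueError, match="reference TS"):
            loss_l1([model.forward(bare)], [bare])

    def test_gradient_matches_finite_differences(self, small_dataset,
                                                 tiny_configs):
        mcfg, fcfg = tiny_configs
        model = randomize_heads(PSIModel(mcfg, fcfg), seed=4)
        rxns = small_dataset[:2]

        def value():
            return float(loss_l1(model.forward_batch(rxns), rxns).data)

        loss = loss_l1(model.forward_batch(rxns), rxns)
        model.zero_grad()
        loss.backward()
        params = dict(model.named_parameters())
        rng = np.random.default_rng(0)
        h = 1e-6
        for name in ["ratio_head.fc2.w", "embed", "psi0.gru.fwd.w"]:
            p = params[name]
            flat = p.data.ravel()
            k = int(rng.integers(flat.size))
            orig = flat[k]
            flat[k] = orig + h
            fp = value()
            flat[k] = orig - h
            fm = value()
            flat[k] = orig
            gfd = (fp - fm) / (2 * h)
            ga = p.grad.ravel()[k]
            assert ga == pytest.approx(gfd, rel=1e-4, abs=1e-9)


class TestLossL2:
    @pytest.fixture()
    def prop_model(self, tiny_configs):
        mcfg, fcfg = tiny_configs
        mcfg = ModelConfig(**{**mcfg.to_dict(), "property_head": True})
        return randomize_heads(PSIModel(mcfg, fcfg), seed=6)

    def test_predictions_equal_labels_give_zero(self, prop_model, small_dataset):
        rxns = small_dataset[:2]
        outs = prop_model.forward_batch(rxns)
        for out, rxn in zip(outs, rxns):
            for role in ("reactant", "product"):
                mol = out.molecular_properties()[role].data
                rxn.properties[role] = dict(zip(("E", "S_vib", "S_rot"), mol))
        assert float(loss_l2(outs, rxns).data) == pytest.approx(0.0, abs=1e-12)

    def test_energy_only_labels_reduce_to_energy_mae(self, prop_model,
                                                     small_dataset):
        import copy

        rxns = [copy.deepcopy(r) for r in small_dataset[:2]]
        for r in rxns:
            r.properties = {role: {"E": r.properties[role]["E"]}
                            for role in ("reactant", "product")}
        outs = prop_model.forward_batch(rxns)
        l2 = float(loss_l2(outs, rxns).data)
        manual = 0.0
        for role in ("reactant", "product"):
            errs = [abs(float(out.molecular_properties()[role].data[0])
                        - r.properties[role]["E"])
                    for out, r in zip(outs, rxns)]
            manual += np.mean(errs)
        assert l2 == pytest.approx(manual)

    def test_doubling_contributions_doubles_molecular_property(self, prop_model,
                                                               small_dataset):
        out = prop_model.forward(small_dataset[0])
        mol = out.molecular_properties()["reactant"].data
        out.atomic_props["reactant"] = out.atomic_props["reactant"] * 2.0
        assert np.allclose(out.molecular_properties()["reactant"].data, 2 * mol)


class TestLossL3:
    def test_zero_for_realizable_point_sets(self):
        rng = np.random.default_rng(7)
        for n in range(2, 13):
            for _ in range(10):
                x = rng.normal(size=(n, 3)) * 2
                pairs = strict_pairs(n)
                d = np.linalg.norm(x[pairs[:, 0]] - x[pairs[:, 1]], axis=1)
                v = edm_penalty_value(d, pairs, n)
                assert abs(v) <= 1e-8 * max(np.sum(d**2), 1.0)

    def test_single_atom_is_zero(self):
        assert edm_penalty_value(np.zeros(0), strict_pairs(1), 1) == 0.0

    def test_positive_for_non_embeddable_distances(self):
        # random "distance" assignments with N well above 5 are generically
        # rank > 5 with a negative residual eigenvalue, hence penalized
        rng = np.random.default_rng(8)
        for n in (8, 10, 12):
            pairs = strict_pairs(n)
            d = rng.uniform(0.5, 3.0, size=pairs.shape[0])
            assert edm_penalty_value(d, pairs, n) > 1e-3

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(9)
        n = 7
        pairs = strict_pairs(n)
        d0 = rng.uniform(0.8, 2.5, size=pairs.shape[0])
        t = Tensor(d0.copy(), requires_grad=True)
        edm_penalty(t, pairs, n).backward()
        h = 1e-6
        for k in rng.integers(0, d0.size, size=6):
            dp, dm = d0.copy(), d0.copy()
            dp[k] += h
            dm[k] -= h
            gfd = (edm_penalty_value(dp, pairs, n)
                   - edm_penalty_value(dm, pairs, n)) / (2 * h)
            assert t.grad[k] == pytest.approx(gfd, rel=1e-4, abs=1e-9)

    def test_batch_loss_is_zero_on_synthetic_references(self, small_dataset,
                                                        tiny_configs):
        mcfg, fcfg = tiny_configs
        model = PSIModel(mcfg, fcfg)
        rxns = small_dataset[:3]
        outs = model.forward_batch(rxns)
        for out, rxn in zip(outs, rxns):
            out.ratios = Tensor(
                rxn.ts_ref.strict_pair_distances(out.pair_index) / out.d_interp)
        assert float(loss_l3(outs, rxns).data) == pytest.approx(0.0, abs=1e-8)


def test_total_loss_weighting(small_dataset, tiny_configs):
    mcfg, fcfg = tiny_configs
    model = randomize_heads(PSIModel(mcfg, fcfg), seed=10)
    rxns = small_dataset[:2]
    outs = model.forward_batch(rxns)
    _, parts0 = total_loss(outs, rxns, c=2000.0, c_prime=0.0)
    assert parts0["L"] == pytest.approx(2000.0 * parts0["L1"])
    assert "L3" not in parts0  # c' = 0 skips the auxiliary terms entirely
    outs = model.forward_batch(rxns)
    _, parts1 = total_loss(outs, rxns, c=1.0, c_prime=10.0)
    assert parts1["L"] == pytest.approx(parts1["L1"] + 10.0 * parts1["L3"])
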