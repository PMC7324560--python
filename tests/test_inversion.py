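import numpy as np
import pytest

from aptrans import apmodel as ap
from aptrans.biomarkers import BiomarkerSet
from aptrans.engine import BiomarkerSimulator
from aptrans.inversion import (
    DoseRecord,
    DoseResponseDataset,
    InversionConfig,
    cost_terms,
    default_weights,
    invert,
    total_cost,
)
from aptrans.pharmacology import DrugSpec
from aptrans.synthetic import SyntheticDesign, generate_dataset, drug_for_block


def _bm(apd50=200.0, apd_step=10.0, v_max=35.0, v_min=-85.0, dvdt=100.0):
    apd = {p: apd50 + apd_step * (p - 50) / 10 for p in range(20, 100, 10)}
    return BiomarkerSet(apd=apd, v_max=v_max, v_min=v_min, dvdt_max=dvdt)


class StubSimulator:
    """Returns fixed biomarkers regardless of parameters (for cost math)."""

    def __init__(self, bm):
        self._bm = bm

    def biomarkers(self, lambdas=None, blocks=None):
        return self._bm


# ------------------------------------------------------------- cost terms


def test_cost_terms_zero_at_equality():
    bm = _bm()
    assert all(v == 0.0 for v in cost_terms(bm, bm, include_dvdt=True).values())


def test_cost_terms_relative_absolute_difference():
    model = _bm(apd50=110.0)
    data = _bm(apd50=100.0)
    terms = cost_terms(model, data)
    assert terms["apd50"] == pytest.approx(0.1)
    # |(-80) - (-85)| / |-85|
    model2 = _bm(v_min=-80.0)
    data2 = _bm(v_min=-85.0)
    assert cost_terms(model2, data2)["v_min"] == pytest.approx(5 / 85)


def test_cost_terms_zero_data_rejected():
    with pytest.raises(ValueError, match="undefined"):
        cost_terms(_bm(), _bm(dvdt=0.0), include_dvdt=True)


# ---------------------------------------------------------------- weights


def test_default_weights_follow_rules():
    w = default_weights(2, include_dvdt=True)
    assert w[(1, "apd90")] == 5
    assert w[(0, "apd90")] == 10  # control multiplied by n_doses
    assert w[(1, "apd50")] == 2
    assert w[(1, "v_max")] == 2 and w[(1, "v_min")] == 2
    assert w[(1, "apd20")] == 1
    assert w[(1, "dvdt_max")] == 1
    # control-only dataset: multiplier 1
    w1 = default_weights(1)
    assert w1[(0, "apd90")] == 5
    with pytest.raises(ValueError):
        default_weights(0)


# ------------------------------------------------------------- total cost


def _control_dataset(bm):
    return DoseResponseDataset(
        species_name="human", dose_unit="uM", records=(DoseRecord(0.0, bm),)
    )


def test_total_cost_hand_example():
    """One discrepant term (APD50, 10% off, weight 2, multiplier 1)."""
    data = _bm(apd50=100.0)
    model = _bm(apd50=100.0)
    model.apd[50] = 110.0
    ds = _control_dataset(data)
    cfg = InversionConfig(free_epsilons=())
    cost = total_cost({}, {}, ds, cfg, StubSimulator(model))
    assert cost == pytest.approx(2 * 0.1**2)


def test_total_cost_linear_in_weights():
    data = _bm(apd50=100.0, v_max=30.0)
    model = _bm(apd50=107.0, v_max=33.0)
    ds = _control_dataset(data)
    cfg1 = InversionConfig(free_epsilons=())
    doubled = {t: 2 * w for t, w in
               {"apd50": 2.0, "apd90": 5.0, "v_max": 2.0, "v_min": 2.0,
                **{f"apd{p}": 1.0 for p in (20, 30, 40, 60, 70, 80)}}.items()}
    cfg2 = InversionConfig(free_epsilons=(), weights=doubled)
    sim = StubSimulator(model)
    assert total_cost({}, {}, ds, cfg2, sim) == pytest.approx(
        2 * total_cost({}, {}, ds, cfg1, sim)
    )


def test_total_cost_penalizes_failed_simulation():
    class FailingSim:
        def biomarkers(self, lambdas=None, blocks=None):
            raise ValueError("no action potential detected")

    ds = _control_dataset(_bm())
    cfg = InversionConfig(free_epsilons=())
    cost = total_cost({}, {}, ds, cfg, FailingSim())
    assert cost == pytest.approx(1e6)


def test_total_cost_zero_at_generating_parameters(zebrafish):
    """Noiseless self-generated data evaluated at the truth costs ~0."""
    sim = BiomarkerSimulator(zebrafish, warm_beats=10, eval_beats=6)
    drug = drug_for_block("d", {"I_Kr": 0.5}, dose=2.0)
    design = SyntheticDesign(
        base_species=zebrafish,
        true_drug=drug,
        doses=(0.0, 2.0),
        perturbation={"I_Kr": 1.1},
    )
    dataset, truth = generate_dataset(design, simulator=sim)
    cfg = InversionConfig(free_epsilons=("I_Kr",), include_dvdt_term=True)
    cost = total_cost(truth.lambdas, truth.epsilons, dataset, cfg, sim)
    assert cost < 1e-6


# ------------------------------------------------------------- validation


def test_dataset_requires_control_and_distinct_doses():
    bm = _bm()
    with pytest.raises(ValueError, match="control"):
        DoseResponseDataset("human", "uM", (DoseRecord(1.0, bm),))
    with pytest.raises(ValueError, match="distinct"):
        DoseResponseDataset(
            "human", "uM", (DoseRecord(0.0, bm), DoseRecord(0.0, bm))
        )


def test_invert_rejects_epsilon_on_missing_channel(human):
    ds = _control_dataset(_bm())
    cfg = InversionConfig(free_epsilons=("I_CaT",))  # human has no I_CaT
    with pytest.raises(ValueError, match="zero conductance"):
        invert(ds, cfg, human)


# ---------------------------------------------------- small end-to-end fit


@pytest.fixture(scope="module")
def small_fit(zebrafish):
    """Control-only self-consistency fit with a tiny schedule."""
    sim = BiomarkerSimulator(zebrafish, warm_beats=10, eval_beats=6)
    design = SyntheticDesign(
        base_species=zebrafish,
        true_drug=DrugSpec("none", (), "uM"),
        doses=(0.0,),
    )
    dataset, _ = generate_dataset(design, simulator=sim)
    cfg = InversionConfig(
        free_epsilons=(),
        free_lambdas=("I_Kr", "I_CaL"),
        continuation_iterations=2,
        guesses_per_iteration=3,
        nm_iterations=5,
        rng_seed=11,
        warm_beats=10,
        eval_beats=6,
    )
    return dataset, cfg, invert(dataset, cfg, zebrafish, simulator=sim), sim


def test_control_only_recovery_near_unity(small_fit):
    _, _, result, _ = small_fit
    # data generated at lambda = 1: incumbent starts at the truth and stays
    for lam in result.lambda_hat.values():
        assert 0.95 <= lam <= 1.05
    assert result.final_cost < 1e-3


def test_incumbent_cost_trace_non_increasing(small_fit):
    _, _, result, _ = small_fit
    trace = result.cost_trace
    assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))


def test_inversion_deterministic_under_seed(small_fit, zebrafish):
    dataset, cfg, result, sim = small_fit
    again = invert(dataset, cfg, zebrafish, simulator=sim)
    assert again.lambda_hat == result.lambda_hat
    assert again.epsilon_hat == result.epsilon_hat
    assert again.cost_trace == result.cost_trace
    assert again.final_cost == result.final_cost
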