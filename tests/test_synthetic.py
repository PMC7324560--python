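import numpy as np
import pytest

from aptrans.engine import BiomarkerSimulator
from aptrans.pharmacology import DrugSpec
from aptrans.synthetic import (
    SyntheticDesign,
    drug_for_block,
    generate_dataset,
)


def test_drug_for_block_fifty_percent_is_reciprocal_dose():
    drug = drug_for_block("d", {"I_Na": 0.5, "I_CaL": 0.5}, dose=4.0)
    assert drug.epsilons == {"I_Na": 0.25, "I_CaL": 0.25}
    # 75% block at dose D: eps = 3/D
    drug2 = drug_for_block("d", {"I_Kr": 0.75}, dose=2.0)
    assert drug2.epsilons["I_Kr"] == pytest.approx(1.5)
    with pytest.raises(ValueError):
        drug_for_block("d", {"I_Kr": 1.0}, dose=1.0)


def test_design_validation():
    import aptrans.apmodel as ap

    zf = ap.species_defaults("zebrafish")
    drug = DrugSpec("none", (), "uM")
    with pytest.raises(ValueError, match="control"):
        SyntheticDesign(base_species=zf, true_drug=drug, doses=(1.0,))
    with pytest.raises(ValueError, match="distinct"):
        SyntheticDesign(base_species=zf, true_drug=drug, doses=(0.0, 0.0))
    with pytest.raises(ValueError):
        SyntheticDesign(
            base_species=zf, true_drug=drug, doses=(0.0,), perturbation={"I_Kr": 0}
        )


@pytest.fixture(scope="module")
def small_sim(zebrafish):
    return BiomarkerSimulator(zebrafish, warm_beats=10, eval_beats=6)


def test_identity_design_reproduces_control(zebrafish, small_sim):
    """No perturbation, no drug, no noise: biomarkers equal the base model's."""
    design = SyntheticDesign(
        base_species=zebrafish, true_drug=DrugSpec("none", (), "uM"), doses=(0.0,)
    )
    dataset, truth = generate_dataset(design, simulator=small_sim)
    control = small_sim.biomarkers()
    rec = dataset.records[0].biomarkers
    assert rec.apd == control.apd
    assert rec.v_max == control.v_max
    assert truth.noiseless[0.0].apd == control.apd


def test_noise_seed_contract(zebrafish, small_sim):
    drug = drug_for_block("d", {"I_Kr": 0.5}, dose=1.0)
    kwargs = dict(
        base_species=zebrafish,
        true_drug=drug,
        doses=(0.0, 1.0),
        noise_sd={"apd50": 0.05, "v_min": 0.02},
    )
    d1, t1 = generate_dataset(
        SyntheticDesign(rng_seed=3, **kwargs), simulator=small_sim
    )
    d2, _ = generate_dataset(
        SyntheticDesign(rng_seed=3, **kwargs), simulator=small_sim
    )
    d3, t3 = generate_dataset(
        SyntheticDesign(rng_seed=4, **kwargs), simulator=small_sim
    )
    # same seed: identical noisy biomarkers
    assert d1.records[0].biomarkers.apd == d2.records[0].biomarkers.apd
    # different seed: different noise, identical ground truth
    assert d1.records[0].biomarkers.apd[50] != d3.records[0].biomarkers.apd[50]
    assert t1.noiseless[0.0].apd == t3.noiseless[0.0].apd
    # noise applied to the dataset only, never to the ground truth
    assert d1.records[0].biomarkers.apd[50] != t1.noiseless[0.0].apd[50]


def test_zero_noise_sd_reproduces_noiseless_bitwise(zebrafish, small_sim):
    drug = drug_for_block("d", {"I_Kr": 0.5}, dose=1.0)
    kwargs = dict(base_species=zebrafish, true_drug=drug, doses=(0.0, 1.0))
    noiseless, _ = generate_dataset(
        SyntheticDesign(**kwargs), simulator=small_sim
    )
    zero_sd, _ = generate_dataset(
        SyntheticDesign(noise_sd={"apd50": 0.0}, **kwargs), simulator=small_sim
    )
    for ra, rb in zip(noiseless.records, zero_sd.records):
        assert ra.biomarkers.apd == rb.biomarkers.apd
        assert ra.biomarkers.v_max == rb.biomarkers.v_max
        assert ra.biomarkers.v_min == rb.biomarkers.v_min
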