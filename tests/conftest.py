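import pytest

from deqsyn import DrugParams, SimulationConfig, make_deq_design

# Standard synthetic two-drug panel. Anchored at the 1/3-log grid points
# -8.67 / -5.67; hills steep enough (>= ~1.5) that the 7-below/2-above
# ladder represents both plateaus, as the emulated assay design requires.
DRUG_A = DrugParams("drugA", log_ec50=-8.67, hill=1.8)
DRUG_B = DrugParams("drugB", log_ec50=-5.67, hill=1.5)
DRUG_C = DrugParams("drugC", log_ec50=-6.67, hill=1.6)


@pytest.fixture
def pair_drugs():
    return {"drugA": DRUG_A, "drugB": DRUG_B}


@pytest.fixture
def pair_design():
    return make_deq_design("drugA", -8.67, "drugB", -5.67)


def noiseless_config(drugs, model="loewe", alpha=0.0, seed=0, **kw):
    return SimulationConfig(
        drugs=drugs, reference_model=model, synergy_alpha=alpha,
        noise_cv=0.0, experiment_cv=0.0, n_experiments=1, seed=seed, **kw,
    )
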