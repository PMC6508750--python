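import numpy as np
import pytest

from cyctx import CellCycleRates, ModelParams, StageKinetics


@pytest.fixture(scope="session")
def baseline_params() -> ModelParams:
    """Moderate-mean shared-kinetics set used for three-way cross-validation."""
    return ModelParams.shared(
        StageKinetics(lam=1.0, gamma=2.0, nu=5.0, delta=1.0),
        CellCycleRates(0.5, 0.5),
    )


@pytest.fixture(scope="session")
def mesc_kinetics() -> StageKinetics:
    """Oct4-like telegraph kinetics in mouse embryonic stem cells (per hour).

    Mean OFF duration ~108 min, ON ~56 min, synthesis 1.89 per minute,
    mRNA lifetime ~7.14 h.
    """
    return StageKinetics(lam=0.5556, gamma=1.0714, nu=1.89 * 60.0, delta=0.14)


@pytest.fixture(scope="session")
def mesc_cycle() -> CellCycleRates:
    """Mouse-ES-cell stage durations: S1 ~560 min, S2 ~220 min."""
    return CellCycleRates(60.0 / 560.0, 60.0 / 220.0)


@pytest.fixture(scope="session")
def oct4_fold_change_params() -> ModelParams:
    """Stage-resolved Oct4 parameter set (shared synthesis rate).

    Activation drops from 0.5556 to 0.3468 per hour across gene duplication;
    inactivation 1.0714, degradation 17.14 per hour in both stages;
    stage transition rates 0.1071 and 0.2727 per hour.
    """
    return ModelParams(
        stage1=StageKinetics(lam=0.5556, gamma=1.0714, nu=1.0, delta=17.14),
        stage2=StageKinetics(lam=0.3468, gamma=1.0714, nu=1.0, delta=17.14),
        cycle=CellCycleRates(0.1071, 0.2727),
    )


@pytest.fixture(scope="session")
def oracle_param_sets() -> list[ModelParams]:
    """Five moderate-mean sets spanning slow to fast cycling."""
    return [
        ModelParams.shared(
            StageKinetics(lam=1.0, gamma=2.0, nu=5.0, delta=1.0),
            CellCycleRates(0.5, 0.5),
        ),
        ModelParams.shared(
            StageKinetics(lam=0.6, gamma=1.1, nu=8.0, delta=0.8),
            CellCycleRates(0.05, 0.12),  # slow cycling
        ),
        ModelParams.shared(
            StageKinetics(lam=2.0, gamma=0.5, nu=6.0, delta=2.0),
            CellCycleRates(3.0, 2.0),  # fast cycling
        ),
        ModelParams(  # stage-asymmetric kinetics
            stage1=StageKinetics(lam=1.5, gamma=1.0, nu=10.0, delta=2.0),
            stage2=StageKinetics(lam=0.7, gamma=2.0, nu=4.0, delta=1.0),
            cycle=CellCycleRates(0.8, 0.3),
        ),
        ModelParams(  # strong dosage compensation via degradation
            stage1=StageKinetics(lam=0.9, gamma=0.9, nu=6.0, delta=0.7),
            stage2=StageKinetics(lam=0.9, gamma=0.9, nu=6.0, delta=3.0),
            cycle=CellCycleRates(1.2, 4.0),
        ),
    ]


def random_params(rng: np.random.Generator) -> ModelParams:
    """Draw a generic positive parameter set over broad rate ranges."""

    def draw():
        return StageKinetics(*np.exp(rng.uniform(np.log(0.05), np.log(20.0), size=4)))

    return ModelParams(
        stage1=draw(),
        stage2=draw(),
        cycle=CellCycleRates(*np.exp(rng.uniform(np.log(0.05), np.log(20.0), size=2))),
    )
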