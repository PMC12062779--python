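import pytest
from hypothesis import HealthCheck, settings

import probemap as pm

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Per-spot analyte levels for the 15-spot line fixture; spots 9 and 10
#: (indices 8, 9) are deliberately the weakest, still resolvable by the
#: TIC peak picker.
LINE_CONCS = (8.0, 6.0, 9.0, 5.0, 7.0, 10.0, 4.0, 6.0, 3.0, 3.5,
              8.0, 7.0, 9.0, 6.0, 5.0)


def line_surface(concs=LINE_CONCS, zero_spots=(), mz=195.0):
    """Gently tilted conductive surface with one analyte varying along x."""
    def conc(x, y):
        i = int(round(x))
        if i in zero_spots:
            return 0.0
        return concs[i]

    return pm.SurfaceModel(plane=(0.02, 0.0, -1.5),
                           analyte_maps=((mz, conc),))


@pytest.fixture(scope="session")
def line_plan():
    return pm.plan_grid((0, 0), (14, 0), 1.0)


@pytest.fixture(scope="session")
def default_cfgs():
    return pm.MotionConfig(), pm.FeedbackConfig(), pm.MSStreamConfig()


@pytest.fixture(scope="session")
def line_run(line_plan, default_cfgs):
    """Full noiseless 15-spot virtual run (conductance mode)."""
    mcfg, fcfg, mscfg = default_cfgs
    return pm.run_virtual_experiment(line_plan, mcfg, fcfg,
                                     line_surface(), mscfg)


@pytest.fixture(scope="session")
def grid_run():
    """3x3 noiseless run over a flat conductive surface."""
    plan = pm.plan_grid((0, 0), (2, 2), 1.0)
    surface = pm.SurfaceModel(plane=(0.0, 0.0, -2.0),
                              analyte_maps=((195.0, lambda x, y: 5.0),))
    res = pm.run_virtual_experiment(plan, pm.MotionConfig(),
                                    pm.FeedbackConfig(), surface,
                                    pm.MSStreamConfig())
    return plan, res
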