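"""Shared fixtures: reference muscle geometries and reusable steady runs."""

import warnings

import pytest

import wkloop as wk

# the decay-fit span warning fires on short 5 Hz diastoles; it is expected
warnings.filterwarnings("ignore", message="decay segment spans only")


@pytest.fixture(scope="session")
def trab_ref():
    """Typical trabecula: optimal length 1.8 mm, diameter 0.26 mm."""
    return wk.TrabeculaGeometry(L0=1.8e-3, diameter=0.26e-3)


@pytest.fixture(scope="session")
def trab_5hz():
    """Body-temperature preparation: 2.6 mm x 0.26 mm."""
    return wk.TrabeculaGeometry(L0=2.6e-3, diameter=0.26e-3)


@pytest.fixture(scope="session")
def normo():
    return wk.get_preset("normotensive")


@pytest.fixture(scope="session")
def twitch_1hz():
    """Synthetic 3.5 mN twitch for 1 Hz replay runs."""
    return wk.synthesize_twitch(peak=3.5e-3, t_rise=0.04, t_fall=0.12,
                                period=1.0)


def make_replay_config(trab, windkessel, stim_hz=1.0, twitch=None,
                       duration=10.0, **kw):
    vg = wk.default_ventricle(trab)
    cyc = wk.CyclePolicy(
        stimulus_frequency=stim_hz,
        refill_rate=wk.default_refill_rate(vg, stim_hz, trab.L0),
        end_diastolic_length=trab.L0,
    )
    if twitch is None:
        twitch = wk.synthesize_twitch(3.5e-3, 0.04, 0.12, 1.0 / stim_hz)
    return wk.SimConfig(geometry=trab, ventricle=vg, windkessel=windkessel,
                        cycle=cyc, twitch=twitch, duration=duration, **kw)


def make_hill_config(trab, windkessel, stim_hz=5.0, hill=None,
                     duration=2.0, **kw):
    vg = wk.default_ventricle(trab)
    cyc = wk.CyclePolicy(
        stimulus_frequency=stim_hz,
        refill_rate=wk.default_refill_rate(vg, stim_hz, trab.L0),
        end_diastolic_length=trab.L0,
    )
    if hill is None:
        hill = (wk.HillMuscleParams.body_temperature() if stim_hz >= 2
                else wk.HillMuscleParams.room_temperature())
    return wk.SimConfig(geometry=trab, ventricle=vg, windkessel=windkessel,
                        cycle=cyc, muscle_mode="hill", hill=hill,
                        duration=duration, **kw)


@pytest.fixture(scope="session")
def steady_replay_record(trab_ref, normo, twitch_1hz):
    """12 s replay run at the normotensive load, full-rate logging."""
    cfg = make_replay_config(trab_ref, normo, twitch=twitch_1hz,
                             duration=12.0, decimation=1)
    return wk.run(cfg), cfg
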