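import numpy as np
import pytest

from seizurespan import ElectrodeGrid, EcogRecording, SessionTimeline
from seizurespan.synth import PhaseSchedule, SimulationConfig, TreatmentEffect


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def small_sim_config():
    """Down-scaled session (120 Hz, 16 min, treatment at 10 min) so that
    full ECoG simulation stays fast; statistical structure matches the
    default cohort (phase progression, 1-min latency, 0.85 suppression)."""
    return SimulationConfig(
        sample_rate_hz=120.0,
        schedule=PhaseSchedule(
            (
                ("baseline", 0.0, 2.0),
                ("spikes", 2.0, 3.5),
                ("spike_wave", 3.5, 5.0),
                ("multi_spike_wave", 5.0, 6.5),
                ("status_epilepticus", 6.5, 16.0),
            )
        ),
        bicuculline_min=2.0,
        treatment_min=10.0,
    )


@pytest.fixture
def small_bin_range():
    return (-8, 6)


@pytest.fixture
def dcz_timeline():
    def make(treatment_s=600.0, treatment="DCZ", subject="monkey1", bicuculline_s=120.0):
        return SessionTimeline(
            subject_id=subject,
            bicuculline_times_s=(bicuculline_s,),
            treatment_of_record=treatment,
            dcz_times_s=(treatment_s,) if treatment == "DCZ" else (),
            vehicle_time_s=treatment_s if treatment == "vehicle" else None,
        )

    return make


@pytest.fixture
def tiny_recording():
    """Two-contact, 10-s, 100-Hz recording for I/O round trips."""
    def make(rng_seed=0, n_channels=2, duration_s=10.0, fs=100.0):
        rng = np.random.default_rng(rng_seed)
        grid = ElectrodeGrid(n_rows=1, n_cols=n_channels, pitch_mm=2.5)
        samples = rng.normal(0.0, 20.0, size=(n_channels, int(duration_s * fs)))
        return EcogRecording(grid=grid, sample_rate_hz=fs, samples=samples)

    return make
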