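"""Shared fixtures: small scripted monolayer fields for oracle tests."""

from __future__ import annotations

import pytest

from hesquant import GeneratorConfig, build_monolayer, render_dataset
from hesquant.synthetic_scene import GroundTruthEvent


def make_shrink_event(cell_id: int, t_extrusion: float | None = None,
                      t_onset: float | None = None, duration: float = 6.5,
                      loss: float = 25.0,
                      event_class: str = "LCE") -> GroundTruthEvent:
    """A fully chained shrink event at the default (jitter-free) lags."""
    if t_extrusion is not None:
        t_rel = t_extrusion - 1.5
        t_on = t_rel - duration
    else:
        t_on = t_onset
        t_rel = t_on + duration
    t_dep = t_on - 5.0
    t_na = t_dep - 2.4
    t_atp = t_na - 3.0
    return GroundTruthEvent(
        cell_id=cell_id, event_class=event_class, has_shrink=True,
        t_atp_decline=t_atp, t_na_entry=t_na, t_depol=t_dep,
        t_shrink_onset=t_on, t_relaxation=t_rel, t_extrusion=t_extrusion,
        true_vol_loss=loss)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(seed=42, n_cells=12, image_size=(160, 160),
                           n_frames=200, noise_model="none")


@pytest.fixture(scope="session")
def small_geometry(small_config):
    return build_monolayer(small_config)


@pytest.fixture(scope="session")
def noiseless_event_field(small_config, small_geometry):
    """One extruding shrinker, one non-extruding shrinker, one quiet field."""
    truth = [make_shrink_event(3, t_extrusion=60.0, loss=22.0),
             make_shrink_event(7, t_onset=40.0, loss=12.0,
                               event_class="none")]
    return render_dataset(small_config, small_geometry, truth,
                          channels=("phase", "volume_reporter", "calcein",
                                    "dibac", "corona", "atp"))
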