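import numpy as np
import pytest

from mvrmap import localize, synthkit


@pytest.fixture(scope="session")
def acq():
    """Default acquisition constants (65 nm px, 40 ms frames, 130 nm PSF)."""
    return synthkit.AcquisitionParams()


@pytest.fixture(scope="session")
def psf():
    return localize.PsfModel(sigma=130.0)


def make_event(x_nm, y_nm, amplitude=300.0, delay_ms=0.0, stimulus_index=0,
               bouton_id="b0", site_index=0):
    frac = (40.0 - delay_ms) / 40.0
    return synthkit.GroundTruthEvent(
        bouton_id=bouton_id,
        stimulus_index=stimulus_index,
        site_index=site_index,
        x_nm=x_nm,
        y_nm=y_nm,
        delay_ms=delay_ms,
        quantal_amplitude=amplitude,
        amplitude=amplitude * frac,
    )


@pytest.fixture(scope="session")
def render_roi(acq, psf):
    """Render noiseless event(s) and return the full-frame difference ROI."""

    def _render(events, noise=False, seed=0):
        pair = synthkit.render_frame_pair(events, acq, seed=seed, noise=noise)
        return localize.CandidateRoi(
            pixel_window=pair.post - pair.pre,
            window_origin=(0, 0),
            pixel_size_nm=acq.pixel_size_nm,
        )

    return _render
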