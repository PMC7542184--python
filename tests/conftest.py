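import dataclasses

import numpy as np
import pytest

from marrowquant import (SyntheticSpec, analyze_image, default_config,
                         generate_adipose_sheet, generate_marrow_section)
from marrowquant.stain import StainMaps


@pytest.fixture(scope="session")
def marrow_cfg():
    return default_config("marrow").with_(pixel_size=1.0)


@pytest.fixture(scope="session")
def adipo_cfg():
    return default_config("adipo").with_(pixel_size=1.0)


@pytest.fixture(scope="session")
def marrow_section():
    """Default synthetic marrow section (image, truth, annotations)."""
    return generate_marrow_section(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def marrow_output(marrow_section, marrow_cfg):
    image, _truth, annotations = marrow_section
    return analyze_image(image, annotations, marrow_cfg, "fixture")


@pytest.fixture(scope="session")
def clean_section():
    """Noise-free render for IoU checks."""
    return generate_marrow_section(SyntheticSpec(seed=3, noise_sd=0.0))


@pytest.fixture(scope="session")
def clean_output(clean_section, marrow_cfg):
    image, _truth, annotations = clean_section
    return analyze_image(image, annotations, marrow_cfg, "clean")


@pytest.fixture(scope="session")
def sheet():
    spec = SyntheticSpec(seed=5, dims=(512, 512), ghost_count=200)
    return generate_adipose_sheet(spec)


@pytest.fixture(scope="session")
def sheet_output(sheet, adipo_cfg):
    image, _truth = sheet
    return analyze_image(image, None, adipo_cfg, "sheet")


def make_stains(eosin, hema=None, white=(240.0, 240.0, 240.0)):
    """StainMaps from plain arrays (for operator-level tests)."""
    eosin = np.asarray(eosin, float)
    hema = np.zeros_like(eosin) if hema is None else np.asarray(hema, float)
    return StainMaps(hema=hema, eosin=eosin,
                     residual=np.zeros_like(eosin),
                     white_reference=np.asarray(white))
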