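import numpy as np
import pytest

from bbbleak import (AcquisitionProtocol, DynamicSeries, PhantomConfig,
                     concentration_from_signal, extract_vif,
                     merge_dual_sequences, patlak_fit, simulate_acquisition)
from bbbleak.phantom import REGION_LABELS, SINUS, TISSUE_REGIONS


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def noise_free_phantom(protocol):
    """Default-grid phantom simulated without noise, plus its ground truth."""
    cfg = PhantomConfig(noise_sd=0.0, seed=7)
    fast, slow, t1_map, masks, truth = simulate_acquisition(cfg, protocol)
    return cfg, fast, slow, t1_map, masks, truth


@pytest.fixture(scope="session")
def quantified_noise_free(noise_free_phantom, protocol):
    """Full quantification chain on the noise-free phantom."""
    cfg, fast, slow, t1_map, masks, truth = noise_free_phantom
    fd = DynamicSeries(fast.data, fast.times, "fast", fast.baseline_count)
    sd = DynamicSeries(slow.data, slow.times, "slow", slow.baseline_count)
    tissue = np.isin(truth.labels, [REGION_LABELS[r] for r in TISSUE_REGIONS])
    conc_fast, _ = concentration_from_signal(fd, t1_map, protocol,
                                             mask=tissue | masks[SINUS])
    conc_slow, _ = concentration_from_signal(sd, t1_map, protocol,
                                             mask=tissue | masks[SINUS])
    merged = merge_dual_sequences(conc_fast, conc_slow)
    vif = extract_vif(merged, masks[SINUS], protocol.hematocrit)
    ki_map = patlak_fit(merged, vif, tissue)
    return cfg, masks, truth, ki_map
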