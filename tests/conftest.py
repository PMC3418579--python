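import numpy as np
import pytest

from ldphasekit.panel_io import GenotypePanel, MarkerMap


def make_panel(dosages, population="test", ids=None) -> GenotypePanel:
    d = np.asarray(dosages, dtype=np.int8)
    ids = ids or [f"ind{i}" for i in range(d.shape[0])]
    return GenotypePanel(ids, population, d)


def make_map(n_markers, chromosome="1", spacing=10_000, start=1) -> MarkerMap:
    pos = start + spacing * np.arange(n_markers)
    return MarkerMap(
        np.array([f"snp{i}" for i in range(n_markers)], dtype=object),
        np.full(n_markers, chromosome, dtype=object),
        pos,
        np.full(n_markers, "A", dtype=object),
        np.full(n_markers, "G", dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
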