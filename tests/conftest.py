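import numpy as np
import pytest

from sexqc.io import ExpressionMatrix
from sexqc.markers import MarkerPanel, MarkerProbe


@pytest.fixture
def tiny_matrix_tsv(tmp_path):
    """3 probes x 2 samples, plain TSV."""
    path = tmp_path / "matrix.tsv"
    path.write_text(
        "probe_id\ts1\ts2\n"
        "p1\t1.0\t2.0\n"
        "p2\t3.0\t4.0\n"
        "p3\t5.0\t6.0\n"
    )
    return path


@pytest.fixture
def tiny_matrix_series(tmp_path, tiny_matrix_tsv):
    """The same table wrapped in GEO series-matrix delimiters and comments."""
    path = tmp_path / "matrix_series.txt"
    body = tiny_matrix_tsv.read_text()
    path.write_text(
        "!Series_title\t\"a tiny series\"\n"
        "!Series_platform_id\t\"GPL570\"\n"
        "!series_matrix_table_begin\n"
        + body
        + "!series_matrix_table_end\n"
        "!series_matrix_table_trailer_comment\n"
    )
    return path


def _panel(n_xist):
    entries = [MarkerProbe(f"XIST_{i + 1}", "XIST", "female_high") for i in range(n_xist)]
    entries += [
        MarkerProbe("KDM5D_1", "KDM5D", "male_high"),
        MarkerProbe("RPS4Y1_1", "RPS4Y1", "male_high"),
    ]
    return MarkerPanel(entries, platform="synthetic")


@pytest.fixture
def clean_panel():
    """2 female-marker + 2 male-marker probes."""
    return _panel(2)


@pytest.fixture
def wide_panel():
    """4 female-marker + 2 male-marker probes; corrupting one XIST probe
    still leaves the others above the same-direction correlation threshold."""
    return _panel(4)


def make_matrix_for_panel(panel, sexes, noise_sd=0.1, seed=0, mu_on=10.0, mu_off=5.0):
    """Deterministic two-sex marker matrix matching a panel's probes."""
    rng = np.random.default_rng(seed)
    rows = []
    for entry in panel.entries:
        base = [
            mu_on if ((s == "female") == (entry.direction == "female_high")) else mu_off
            for s in sexes
        ]
        rows.append(np.asarray(base) + rng.normal(0, noise_sd, len(sexes)))
    sample_ids = [f"s{i + 1}" for i in range(len(sexes))]
    return ExpressionMatrix(panel.probe_ids, sample_ids, np.vstack(rows))
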