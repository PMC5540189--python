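import numpy as np
import pandas as pd
import pytest

from qccmap.cell_table import MarkerPanel, SectionTable


def build_section(
    akt,
    h3k9me2,
    hes1,
    tissue_class=None,
    x=None,
    y=None,
    fov_id="F00",
    tile=(2000.0, 2000.0),
    section_id="S1",
    fovs=None,
):
    """Single- or multi-FOV section from raw marker arrays (test helper)."""
    n = len(akt)
    panel = MarkerPanel()
    if tissue_class is None:
        tissue_class = ["tumor"] * n
    if x is None:
        x = np.linspace(0, tile[0] * 0.9, n)
    if y is None:
        y = np.zeros(n)
    fov_col = [fov_id] * n if isinstance(fov_id, str) else list(fov_id)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "fov_id": fov_col,
            "x_local": x,
            "y_local": y,
            "tissue_class": tissue_class,
            "AKT_cytoplasm_mean": akt,
            "H3K9me2_nuclear_mean": h3k9me2,
            "HES1_cytoplasm_mean": hes1,
        }
    )
    if fovs is None:
        fovs = pd.DataFrame(
            [
                {
                    "fov_id": f,
                    "grid_row": 0,
                    "grid_col": i,
                    "tile_width": tile[0],
                    "tile_height": tile[1],
                    "tumor_fraction": 0.5,
                    "artifact_fraction": 0.0,
                }
                for i, f in enumerate(dict.fromkeys(fov_col))
            ]
        )
    return SectionTable(section_id=section_id, cells=cells, fovs=fovs, panel=panel)


@pytest.fixture
def four_cell_section():
    """The worked 4-cell example: AKT=[1,2,3,4], H3K9me2=[1,2,3,4], HES1=[4,3,2,1].

    At t=0.25 cell 0 is the unique QCC (low AKT, low H3K9me2, high HES1).
    """
    return build_section(
        akt=[1.0, 2.0, 3.0, 4.0],
        h3k9me2=[1.0, 2.0, 3.0, 4.0],
        hes1=[4.0, 3.0, 2.0, 1.0],
    )


@pytest.fixture
def square_xy():
    """4 cells at the corners of two 1-px-apart vertical pairs, 10 px apart."""
    return np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)
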