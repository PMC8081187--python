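"""Standard 10-20 montage used by the synthetic generator and topography helpers.

Positions are 2-D head-circle coordinates (x: left(-) to right(+), y: back(-)
to front(+), unit head radius) for the 30 scalp channels of a 32-electrode
BrainAmp-style cap after dropping ECG and ground.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_montage", "channel_names", "gaussian_topography"]


def load_montage() -> pd.DataFrame:
    """Return the shipped montage as a DataFrame indexed by channel name."""
    with resources.files("tactile_p300.data").joinpath("montage_1020.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("name")


def channel_names() -> list[str]:
    """Channel names of the default 30-channel montage, cap order."""
    return list(load_montage().index)


def gaussian_topography(
    center: tuple[float, float],
    width: float,
    names: list[str] | None = None,
) -> np.ndarray:
    """Per-channel gain vector: isotropic Gaussian on the 2-D montage.

    Parameters
    ----------
    center : (x, y) of the maximum in montage coordinates.
    width : Gaussian sigma in head-radius units.
    names : channels to evaluate at; defaults to the full montage.

    Returns a vector normalised to a maximum of 1.
    """
    mont = load_montage()
    if names is None:
        names = list(mont.index)
    xy = mont.loc[names, ["x", "y"]].to_numpy(float)
    d2 = ((xy - np.asarray(center, float)) ** 2).sum(axis=1)
    g = np.exp(-d2 / (2.0 * width**2))
    return g / g.max()
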