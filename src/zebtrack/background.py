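"""Running-extremum background estimation and subtraction.

The background of a behavioral video is estimated as the per-pixel lightest
(or darkest) value seen so far: for a dark subject on a light background, a
pixel's background value is updated whenever the incoming pixel is lighter
than the stored one, so the subject is removed as soon as it has vacated each
pixel once.  Ties do not update; an optional noise threshold requires the
incoming pixel to exceed the stored value by more than the threshold.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BackgroundModel"]


class BackgroundModel:
    """Per-pixel running-extremum background.

    Parameters
    ----------
    pixel_search : {"lightest", "darkest"}
        Which extremum to keep.  "lightest" suits a dark subject on a light
        background; "darkest" the inverse.
    noise_threshold : float
        Minimum intensity difference an incoming pixel must exceed before it
        replaces the stored value.  Applied symmetrically in both modes.
    """

    def __init__(self, pixel_search: str = "lightest", noise_threshold: float = 0.0):
        if pixel_search not in ("lightest", "darkest"):
            raise ValueError("pixel_search must be 'lightest' or 'darkest'")
        if noise_threshold < 0:
            raise ValueError("noise_threshold must be >= 0")
        self.pixel_search = pixel_search
        self.noise_threshold = float(noise_threshold)
        self.image: np.ndarray | None = None

    def update(self, frame: np.ndarray) -> np.ndarray:
        """Fold one frame into the background; returns the background image.

        The first frame initializes the background.
        """
        frame = np.asarray(frame)
        if self.image is None:
            self.image = frame.astype(np.uint8).copy()
            return self.image
        if frame.shape != self.image.shape:
            raise ValueError(
                f"frame shape {frame.shape} does not match background "
                f"{self.image.shape}"
            )
        f = frame.astype(np.int16)
        b = self.image.astype(np.int16)
        if self.pixel_search == "lightest":
            mask = f > b + self.noise_threshold
        else:
            mask = f < b - self.noise_threshold
        self.image[mask] = frame[mask]
        return self.image

    def subtract(self, frame: np.ndarray) -> np.ndarray:
        """Clipped foreground image; the subject comes out bright.

        In "lightest" mode (dark subject) this is ``clip(background - frame)``;
        in "darkest" mode, ``clip(frame - background)``.  Never negative.
        """
        if self.image is None:
            raise ValueError("background not initialized")
        frame = np.asarray(frame)
        if frame.shape != self.image.shape:
            raise ValueError(
                f"frame shape {frame.shape} does not match background "
                f"{self.image.shape}"
            )
        f = frame.astype(np.int16)
        b = self.image.astype(np.int16)
        diff = b - f if self.pixel_search == "lightest" else f - b
        return np.clip(diff, 0, 255).astype(np.uint8)
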