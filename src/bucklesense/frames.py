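"""Coordinate-snapshot container shared by the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

#: Recognised bead roles.
ROLE_MEMBRANE = "membrane_head"
ROLE_PROTEIN = "protein_backbone"
ROLE_OTHER = "other"


@dataclass
class LabeledFrame:
    """One snapshot: bead coordinates (nm), per-bead roles, periodic box.

    ``coords`` is an (N, 3) float array in nm; ``roles`` an (N,) array of
    strings (``membrane_head`` / ``protein_backbone`` / ``other``); ``box``
    the three periodic box lengths in nm; ``time`` the frame time in ps.
    """

    coords: np.ndarray
    roles: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.roles = np.asarray(self.roles, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DomainError("coords must be an (N, 3) array")
        if self.roles.shape != (self.coords.shape[0],):
            raise DomainError("roles length must match coordinate count")
        if not np.all(np.isfinite(self.coords)):
            raise DomainError("non-finite coordinates in frame")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise DomainError("box must be three positive lengths (nm)")

    def _mask(self, role: str) -> np.ndarray:
        # role masks are immutable in practice; cache them per frame
        cache = self.__dict__.setdefault("_mask_cache", {})
        if role not in cache:
            cache[role] = self.roles == role
        return cache[role]

    @property
    def membrane(self) -> np.ndarray:
        """Coordinates of membrane head beads, (Nm, 3) nm."""
        return self.coords[self._mask(ROLE_MEMBRANE)]

    @property
    def protein(self) -> np.ndarray:
        """Coordinates of protein backbone beads, (Np, 3) nm."""
        return self.coords[self._mask(ROLE_PROTEIN)]

    def shifted(self, delta: np.ndarray, wrap_xy: bool = False) -> "LabeledFrame":
        """Return a copy translated by ``delta`` (3-vector, nm).

        With ``wrap_xy`` the x and y coordinates are wrapped back into
        [0, box) after the shift (z is never periodic here).
        """
        coords = self.coords + np.asarray(delta, dtype=float)
        if wrap_xy:
            coords = coords.copy()
            coords[:, 0] %= self.box[0]
            coords[:, 1] %= self.box[1]
        return LabeledFrame(coords, self.roles.copy(), self.box.copy(), self.time)
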