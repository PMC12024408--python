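"""Pedigree container shared by the breeding simulator and kinship code."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NULL_ID = 0


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree (parents precede offspring).

    ``sire``/``dam`` hold animal IDs with 0 as the missing-parent code.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray | None = None
    generation: np.ndarray | None = None
    breed_label: str | None = None
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if len({self.ids.size, self.sire.size, self.dam.size}) != 1:
            raise PedigreeError("id/sire/dam lengths differ")
        self._pos = {int(a): i for i, a in enumerate(self.ids)}
        if len(self._pos) != self.ids.size:
            raise PedigreeError("duplicate animal IDs")
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            for i, pid in enumerate(par):
                if pid == NULL_ID:
                    continue
                j = self._pos.get(int(pid))
                if j is None:
                    raise PedigreeError(
                        f"{name} {pid} of animal {self.ids[i]} not in pedigree")
                if j >= i:
                    raise PedigreeError(
                        f"{name} {pid} does not precede animal {self.ids[i]}"
                        " (pedigree must be topologically ordered)")

    @property
    def n(self) -> int:
        return self.ids.size

    def positions(self, ids) -> np.ndarray:
        """0-based row positions of the given animal IDs."""
        return np.array([self._pos[int(a)] for a in np.atleast_1d(ids)])

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based sire/dam indices, -1 for unknown."""
        s = np.array([self._pos.get(int(a), -1) if a != NULL_ID else -1
                      for a in self.sire])
        d = np.array([self._pos.get(int(a), -1) if a != NULL_ID else -1
                      for a in self.dam])
        return s, d

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.ids, "sire": self.sire, "dam": self.dam})
        if self.sex is not None:
            out["sex"] = self.sex
        if self.generation is not None:
            out["generation"] = self.generation
        return out

    def write(self, path, include_extra: bool = False) -> None:
        """3-column whitespace pedigree file (0 = missing parent)."""
        cols = ["id", "sire", "dam"]
        frame = self.to_frame()
        if include_extra:
            cols = list(frame.columns)
        frame[cols].to_csv(path, sep=" ", index=False, header=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep=r"\s+", header=None)
    sex = df[3].to_numpy() if df.shape[1] > 3 else None
    gen = df[4].to_numpy() if df.shape[1] > 4 else None
    return Pedigree(ids=df[0].to_numpy(), sire=df[1].to_numpy(),
                    dam=df[2].to_numpy(), sex=sex, generation=gen)
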