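"""Relatedness matrices from colony/patriline pedigrees.

In a haplodiploid, singly-queened, polyandrous colony the sterile workers
fall into paternal half-sib families (patrilines): super-sisters sharing a
father are related 0.75, half-sisters in the same colony 0.25, and workers
of different colonies 0. The general builder accepts any coefficient triple
so the method applies to other known-relatedness group structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import Pedigree

__all__ = ["KinshipMatrix", "build_block_kinship", "build_army_ant_kinship"]

ARMY_ANT_SAME_PATRILINE = 0.75
ARMY_ANT_SAME_COLONY = 0.25
ARMY_ANT_UNRELATED = 0.0


@dataclass
class KinshipMatrix:
    """An n x n symmetric relatedness matrix with unit diagonal."""

    ids: list
    K: np.ndarray

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.ids)
        if self.K.shape != (n, n):
            raise ValueError("K shape does not match the id list")
        if not np.allclose(self.K, self.K.T, atol=1e-12):
            raise ValueError("K must be symmetric")
        if not np.allclose(np.diag(self.K), 1.0, atol=1e-12):
            raise ValueError("K must have unit diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.K)[0])

    def require_psd(self, tol: float = 1e-8) -> None:
        lam = self.min_eigenvalue()
        if lam < -tol:
            raise ValueError(
                f"kinship matrix is not positive semidefinite "
                f"(min eigenvalue {lam:.3g}); the implied trait covariance "
                f"would be invalid"
            )

    def reorder(self, id_order: Sequence[str]) -> "KinshipMatrix":
        index = {sid: i for i, sid in enumerate(self.ids)}
        try:
            perm = [index[str(s)] for s in id_order]
        except KeyError as e:
            raise KeyError(f"specimen {e.args[0]!r} not in kinship matrix")
        return KinshipMatrix(list(map(str, id_order)), self.K[np.ix_(perm, perm)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.K, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(Path(path), index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(float))


def build_block_kinship(
    pedigree: Pedigree,
    id_order: Optional[Sequence[str]] = None,
    same_patriline: float = ARMY_ANT_SAME_PATRILINE,
    same_colony: float = ARMY_ANT_SAME_COLONY,
    unrelated: float = ARMY_ANT_UNRELATED,
    psd_tol: float = 1e-8,
) -> KinshipMatrix:
    """Kinship with coefficients by group: ``same_patriline`` within a
    patriline, ``same_colony`` between patrilines of one colony, ``unrelated``
    across colonies; diagonal 1. Positive semidefiniteness is verified.
    """
    ids = [str(s) for s in (id_order if id_order is not None else pedigree.ids)]
    pairs = {}
    for sid in ids:
        pairs[sid] = pedigree.lookup(sid)  # raises KeyError naming the id
    colony = np.array([pairs[s][0] for s in ids])
    patriline = np.array([pairs[s][1] for s in ids])
    same_col = colony[:, None] == colony[None, :]
    same_pat = same_col & (patriline[:, None] == patriline[None, :])
    K = np.where(same_pat, same_patriline,
                 np.where(same_col, same_colony, unrelated))
    np.fill_diagonal(K, 1.0)
    km = KinshipMatrix(ids, K)
    km.require_psd(psd_tol)
    return km


def build_army_ant_kinship(
    pedigree: Pedigree, id_order: Optional[Sequence[str]] = None
) -> KinshipMatrix:
    """Haplodiploid half-sib kinship: 0.75 same father, 0.25 same colony,
    0 across colonies (single queen per colony, so maternal relatedness is
    carried by the 0.25 baseline)."""
    return build_block_kinship(pedigree, id_order)
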