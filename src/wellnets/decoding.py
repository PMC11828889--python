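"""Meta-analytic decoding of clade maps by spatial correlation.

Each merged clade map is compared with a set of labelled term-association
volumes (e.g. term-based meta-analysis maps exported from a coordinate
database) by demeaned Pearson correlation over the analysis mask.  Per
clade, terms are ranked by descending r and the top k reported; following
common practice only correlations of at least 0.10 are flagged as
interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import UndefinedStatisticError

__all__ = ["DecodingResult", "spatial_pearson", "decode_clades", "INTERPRET_R"]

#: Minimum spatial correlation considered interpretable.
INTERPRET_R = 0.10


@dataclass
class DecodingResult:
    """Spatial correlation of one clade map with one term map."""

    clade: int
    term: str
    r: float
    flagged: bool  # r >= INTERPRET_R


def spatial_pearson(
    map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Demeaned Pearson correlation of two volumes over a mask."""
    a = np.asarray(map_a, dtype=np.float64)
    b = np.asarray(map_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("maps must share one grid")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    av = a[mask]
    bv = b[mask]
    if av.size < 3:
        raise ValueError("need at least 3 mask voxels")
    ac = av - av.mean()
    bc = bv - bv.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        raise UndefinedStatisticError("constant map within mask")
    return float((ac @ bc) / (na * nb))


def decode_clades(
    clade_maps: dict[int, np.ndarray],
    term_maps: dict[str, np.ndarray],
    mask: np.ndarray | None = None,
    top_k: int = 10,
) -> list[DecodingResult]:
    """Ranked term associations for each clade map.

    Computes every clade × term spatial correlation; per clade, returns the
    ``top_k`` terms by descending r (all terms if ``top_k`` exceeds the term
    count).  Ties rank alphabetically by term for determinism.
    """
    results: list[DecodingResult] = []
    for clade in sorted(clade_maps):
        rows = []
        for term in sorted(term_maps):
            r = spatial_pearson(clade_maps[clade], term_maps[term], mask)
            rows.append((term, r))
        rows.sort(key=lambda tr: (-tr[1], tr[0]))
        for term, r in rows[:top_k]:
            results.append(
                DecodingResult(clade=int(clade), term=term, r=r, flagged=r >= INTERPRET_R)
            )
    return results
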