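"""Cell-type composition confound checks.

Two tools: a mutual-nearest-neighbor pairing of probes across two array
designs (pairs kept when each probe is the other's closest and they lie
within 150 bp), and hypergeometric intersection tests of the study's
differential gene list against cell-type-specific gene lists.  Absence of
larger-than-expected intersections (p above a configurable threshold,
default 0.4) argues against a cell-ratio confound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, intersection_test
from .simulate import GenomeLayout

log = logging.getLogger(__name__)


@dataclass
class ProbePairing:
    pairs: pd.DataFrame  # probe_id_a, probe_id_b, distance
    n_unpaired_a: int
    n_unpaired_b: int


def pair_probes(
    design_a: GenomeLayout | pd.DataFrame,
    design_b: GenomeLayout | pd.DataFrame,
    max_dist: int = 150,
) -> ProbePairing:
    """1-1 probe mapping across designs by mutual nearest neighbor.

    A pair (a, b) is kept iff b is a's nearest probe on the same chromosome,
    a is b's nearest, and |start_a - start_b| <= max_dist.  Mutual
    nearest-neighbor matching guarantees the 1-1 property; distances are
    measured between probe start coordinates.
    """
    pa = design_a.probes if isinstance(design_a, GenomeLayout) else design_a
    pb = design_b.probes if isinstance(design_b, GenomeLayout) else design_b
    rows = []
    for chrom in sorted(set(pa["chromosome"]) | set(pb["chromosome"])):
        a = pa.loc[pa["chromosome"] == chrom].sort_values("start", kind="stable")
        b = pb.loc[pb["chromosome"] == chrom].sort_values("start", kind="stable")
        if a.empty or b.empty:
            continue
        a_pos = a["start"].to_numpy()
        b_pos = b["start"].to_numpy()
        nn_ab = _nearest(a_pos, b_pos)
        nn_ba = _nearest(b_pos, a_pos)
        for i, j in enumerate(nn_ab):
            if nn_ba[j] == i:
                d = abs(int(a_pos[i]) - int(b_pos[j]))
                if d <= max_dist:
                    rows.append(
                        (a["probe_id"].iloc[i], b["probe_id"].iloc[j], d)
                    )
    pairs = pd.DataFrame(rows, columns=["probe_id_a", "probe_id_b", "distance"])
    return ProbePairing(
        pairs=pairs,
        n_unpaired_a=len(pa) - len(pairs),
        n_unpaired_b=len(pb) - len(pairs),
    )


def _nearest(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Index of the nearest reference position for each query position.

    Ties (equidistant neighbors) resolve to the left/lower reference index,
    fixed for determinism.
    """
    idx = np.searchsorted(reference, query)
    idx_right = np.clip(idx, 0, len(reference) - 1)
    idx_left = np.clip(idx - 1, 0, len(reference) - 1)
    d_left = np.abs(query - reference[idx_left])
    d_right = np.abs(query - reference[idx_right])
    return np.where(d_left <= d_right, idx_left, idx_right)


def celltype_intersection_tests(
    dm_genes: set[str],
    celltype_lists: dict[str, set[str]],
    universe: set[str],
    threshold: float = 0.4,
) -> pd.DataFrame:
    """Intersection test against each cell-type-specific list.

    A result with p > threshold is consistent with no cell-composition
    confound for that comparison.
    """
    rows = []
    for name, genes in celltype_lists.items():
        res: EnrichmentResult = intersection_test(dm_genes, genes, universe)
        rows.append((name, res.N, res.K, res.n, res.k, res.p, res.p > threshold))
    return pd.DataFrame(
        rows, columns=["celltype_list", "N", "K", "n", "k", "p", "no_confound"]
    )
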