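"""Site-combination labels for negative-RAD genes and hierarchical
clustering of the RAD matrix.

A gene's *pattern* for one patient is the concatenation, in OV/PE/LN order,
of exactly the tumor sites where the gene carries a significant negative
RAD call — e.g. ``PELN`` for a gene whose variant allele is preferentially
expressed in both metastasis sites but not the primary.  Eight labels are
possible: OV, PE, LN, OVPE, OVLN, PELN, OVPELN and none.

The RAD matrix (variants x sample-sites) uses -2 as the sentinel for
expressed-nowhere variants — visibly below the valid [-1, 1] range — and
NaN for untested cells.  For clustering distances only, untested cells are
imputed as 0 (no preferential expression); pattern assignment never imputes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from skbio.tree import TreeNode

from .records import TUMOR_SITE_ORDER

__all__ = [
    "SitePatternAssignment",
    "assign_site_pattern",
    "build_rad_matrix",
    "cluster_rad_matrix",
]

PATTERNS = ("OV", "PE", "LN", "OVPE", "OVLN", "PELN", "OVPELN", "none")


@dataclass(frozen=True)
class SitePatternAssignment:
    gene: str
    patient: str
    pattern: str
    per_site_rad: dict


def assign_site_pattern(
    gene: str,
    patient: str,
    site_classes: Mapping[str, str],
    per_site_rad: Mapping[str, float] | None = None,
) -> SitePatternAssignment:
    """Label a (gene, patient) by the sites with a negative class.

    ``site_classes`` maps site -> aggregate class for that gene at that
    site; missing sites count as non-negative (absence of evidence is not
    negative RAD).  Raises on an empty mapping.
    """
    if not site_classes:
        raise ValueError("no per-site classes supplied")
    unknown = set(site_classes) - set(TUMOR_SITE_ORDER)
    if unknown:
        raise ValueError(f"unknown sites: {sorted(unknown)}")
    negative_sites = [
        s for s in TUMOR_SITE_ORDER if site_classes.get(s) == "negative"
    ]
    pattern = "".join(negative_sites) or "none"
    return SitePatternAssignment(
        gene=gene,
        patient=patient,
        pattern=pattern,
        per_site_rad=dict(per_site_rad or {}),
    )


def build_rad_matrix(
    results: pd.DataFrame, sentinel: float = -2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot per-variant calls into a variants x sample-sites RAD matrix.

    ``results`` needs columns variant_id, patient, site, rad, klass.
    Returns ``(matrix, provenance)`` with identical shape: matrix cells hold
    the RAD value, the sentinel for not_expressed calls, or NaN where
    untested; provenance flags each cell as ``rad`` / ``not_expressed`` /
    ``missing``.
    """
    if abs(sentinel) <= 1.0:
        raise ValueError("sentinel must lie outside the valid RAD range [-1, 1]")
    df = results.copy()
    df["column"] = df["patient"].astype(str) + "_" + df["site"].astype(str)
    df["cell"] = np.where(df["klass"] == "not_expressed", sentinel, df["rad"])
    matrix = df.pivot_table(
        index="variant_id", columns="column", values="cell", aggfunc="first"
    )
    flag = df.assign(
        flag=np.where(df["klass"] == "not_expressed", "not_expressed", "rad")
    ).pivot_table(
        index="variant_id", columns="column", values="flag", aggfunc="first"
    )
    flag = flag.reindex(index=matrix.index, columns=matrix.columns).fillna("missing")
    matrix = matrix.sort_index()
    flag = flag.sort_index()
    return matrix, flag


def _linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    tree = TreeNode.from_linkage_matrix(link, list(labels))
    return str(tree).strip()


def cluster_rad_matrix(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "average",
) -> dict:
    """Agglomerative clustering of rows (and, when possible, columns).

    Untested cells (NaN) are imputed as 0 for the distance computation
    only.  Deterministic: identical input yields identical linkage and leaf
    order (scipy breaks ties by original index order).  Returns a dict with
    row/col orders (label lists), linkage matrices and Newick dendrograms.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    filled = matrix.fillna(0.0)
    out: dict = {}
    row_link = hierarchy.linkage(filled.to_numpy(), method=linkage, metric=distance)
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    out["row_linkage"] = row_link
    out["row_order"] = row_order
    out["row_newick"] = _linkage_to_newick(row_link, [str(i) for i in matrix.index])
    if matrix.shape[1] >= 2:
        col_link = hierarchy.linkage(
            filled.to_numpy().T, method=linkage, metric=distance
        )
        out["col_linkage"] = col_link
        out["col_order"] = [matrix.columns[i] for i in hierarchy.leaves_list(col_link)]
        out["col_newick"] = _linkage_to_newick(
            col_link, [str(c) for c in matrix.columns]
        )
    else:
        out["col_linkage"] = None
        out["col_order"] = list(matrix.columns)
        out["col_newick"] = None
    return out
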