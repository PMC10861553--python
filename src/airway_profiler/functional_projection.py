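"""Projection of community abundances onto isolate gene content.

Given per-sample OTU relative abundances, identity hits linking OTUs to
cultured isolates, and the isolate x KO presence/absence matrix, the
community's *functional potential* is the matrix product F = A.K: each
sample's expected KO content, a proxy for the metabolic capabilities (and
hence expected metabolite turnover) of its community.

An OTU's abundance is split equally among its admissible isolate hits
(identity-weighted splitting is available); abundance with no admissible
hit is reported as an unmapped fraction rather than renormalised, keeping
F comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_prep import OTUTable
from .isolate_mapping import BIN_CODES, IdentityHit
from .ko_profiles import KOProfileMatrix

__all__ = ["FunctionalPotential", "abundance_to_isolates", "project_functional_potential"]


@dataclass(frozen=True)
class FunctionalPotential:
    """Samples x KO real-valued functional potential matrix F = A.K."""

    F: pd.DataFrame

    def __post_init__(self):
        if (self.F.to_numpy() < -1e-12).any():
            raise ValueError("functional potential must be non-negative")


def abundance_to_isolates(
    t: OTUTable,
    hits: list[IdentityHit],
    min_bin: int = 3,
    weighting: str = "equal",
) -> tuple[pd.DataFrame, pd.Series]:
    """Distribute per-sample OTU relative abundance over isolate hits.

    Only hits whose identity bin code is >= ``min_bin`` (default 3, the
    >=99% class) are admissible.  ``weighting="equal"`` splits an OTU's
    abundance equally across its admissible isolates;
    ``weighting="identity"`` splits proportionally to percent identity.
    Returns the samples x isolates abundance matrix and the per-sample
    unmapped fraction (abundance of OTUs with no admissible hit).
    """
    if weighting not in ("equal", "identity"):
        raise ValueError("weighting must be 'equal' or 'identity'")
    if min_bin not in (1, 2, 3):
        raise ValueError("min_bin must be 1, 2 or 3")
    rel = t.relative_abundance()
    admissible: dict[str, list[IdentityHit]] = {}
    isolates: list[str] = []
    for h in hits:
        if BIN_CODES[h.bin] >= min_bin:
            admissible.setdefault(h.otu_id, []).append(h)
            if h.isolate_id not in isolates:
                isolates.append(h.isolate_id)
    if not admissible:
        import warnings

        warnings.warn("no admissible OTU->isolate hits; abundance matrix is empty")
        return (pd.DataFrame(0.0, index=rel.index, columns=[]),
                pd.Series(1.0, index=rel.index, name="unmapped"))
    A = pd.DataFrame(0.0, index=rel.index, columns=isolates)
    mapped = pd.Series(0.0, index=rel.index)
    for otu, otu_hits in admissible.items():
        if otu not in rel.columns:
            continue
        ab = rel[otu]
        if weighting == "equal":
            w = np.full(len(otu_hits), 1.0 / len(otu_hits))
        else:
            pid = np.array([h.percent_identity for h in otu_hits])
            w = pid / pid.sum()
        for h, wi in zip(otu_hits, w):
            A[h.isolate_id] += ab * wi
        mapped += ab
    unmapped = (1.0 - mapped).clip(lower=0.0)
    unmapped.name = "unmapped"
    return A, unmapped


def project_functional_potential(
    A: pd.DataFrame, K: KOProfileMatrix, ko_subset=None
) -> FunctionalPotential:
    """Multiply sample x isolate abundances by the KO presence/absence matrix.

    Isolate ids of ``A`` must be a subset of the KO matrix's isolates.
    ``ko_subset`` optionally restricts the projection to a KO panel (e.g.
    metabolite-linked KOs); restriction commutes with the product.
    """
    unknown = set(A.columns) - set(K.isolate_ids)
    if unknown:
        raise KeyError(f"isolates absent from KO matrix: {sorted(unknown)[:5]}")
    kdf = K.to_frame()
    if ko_subset is not None:
        missing = set(ko_subset) - set(kdf.columns)
        if missing:
            raise KeyError(f"unknown KOs in subset: {sorted(missing)[:5]}")
        kdf = kdf[list(ko_subset)]
    if len(A.columns) == 0:
        return FunctionalPotential(pd.DataFrame(0.0, index=A.index, columns=kdf.columns))
    F = A.to_numpy() @ kdf.loc[list(A.columns)].to_numpy().astype(float)
    return FunctionalPotential(pd.DataFrame(F, index=A.index, columns=kdf.columns))
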