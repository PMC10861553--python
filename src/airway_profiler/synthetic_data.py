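"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed: planted
KO matrices with cluster-specific gene signatures and flip noise, count
tables drawn from a Dirichlet-multinomial mixture, a low-biomass
contamination model in which a contaminant contributes a constant
absolute input against a biomass gradient, and point-mutated 16S
sequences at exact substitution counts.  Ground truth (labels, planted
parameters) is returned alongside every artifact so recovery can be
measured end to end.

A single user seed fans out to independent per-generator substreams via
``rng_for(seed, name)`` (a ``SeedSequence`` keyed on the seed and a CRC of
the generator name), so adding a generator never perturbs the streams of
the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_prep import OTUTable
from .dmm_typing import CompositionCounts
from .ko_profiles import KOProfileMatrix

__all__ = [
    "SyntheticTruth",
    "rng_for",
    "simulate_ko_matrix",
    "simulate_collection_ko_matrix",
    "COLLECTION_CLUSTER_SIZES",
    "simulate_dmm_counts",
    "airway_cohort_parameters",
    "simulate_airway_cohort",
    "simulate_contaminated_community",
    "random_sequence",
    "mutate_16s",
]


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Independent substream for one named generator under a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated artifact; fields are generator-specific."""

    seed: int
    cluster_labels: dict[str, int] | None = None
    signature_kos: dict[int, list[str]] | None = None
    flip_rate: float | None = None
    planted_counts: dict[str, int] | None = None
    dmm_pi: np.ndarray | None = None
    dmm_alpha: np.ndarray | None = None
    dmm_labels: np.ndarray | None = None
    depths: np.ndarray | None = None
    contaminant_otus: list[str] = field(default_factory=list)
    contaminant_input: float | None = None
    biomass: np.ndarray | None = None
    mutation_count: int | None = None


# ---------------------------------------------------------------------------
# planted KO matrices

def simulate_ko_matrix(
    n_clusters: int = 3,
    isolates_per_cluster: int = 10,
    n_background_kos: int = 100,
    signature_size: int = 30,
    flip_rate: float = 0.0,
    seed: int = 0,
) -> tuple[KOProfileMatrix, SyntheticTruth]:
    """Planted-partition binary KO matrix.

    Background KOs are present independently with probability 0.5; each
    cluster owns a disjoint block of ``signature_size`` KOs present only
    in its members.  Every cell is then flipped independently with
    probability ``flip_rate``.
    """
    if min(n_clusters, isolates_per_cluster, n_background_kos, signature_size) < 1:
        raise ValueError("all size parameters must be positive")
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5)")
    rng = rng_for(seed, "ko_matrix")
    n_iso = n_clusters * isolates_per_cluster
    n_sig = n_clusters * signature_size
    n_kos = n_background_kos + n_sig
    labels = np.repeat(np.arange(1, n_clusters + 1), isolates_per_cluster)
    mat = np.zeros((n_iso, n_kos), dtype=np.uint8)
    mat[:, :n_background_kos] = rng.random((n_iso, n_background_kos)) < 0.5
    for c in range(n_clusters):
        cols = slice(n_background_kos + c * signature_size,
                     n_background_kos + (c + 1) * signature_size)
        mat[labels == c + 1, cols] = 1
    if flip_rate > 0:
        flips = rng.random(mat.shape) < flip_rate
        mat = np.where(flips, 1 - mat, mat).astype(np.uint8)
    isolate_ids = [f"ISO{c:02d}_{i:02d}" for c in range(1, n_clusters + 1)
                   for i in range(isolates_per_cluster)]
    ko_ids = [f"K{j + 1:05d}" for j in range(n_kos)]
    sig = {c + 1: ko_ids[n_background_kos + c * signature_size:
                         n_background_kos + (c + 1) * signature_size]
           for c in range(n_clusters)}
    truth = SyntheticTruth(
        seed=seed,
        cluster_labels=dict(zip(isolate_ids, labels.tolist())),
        signature_kos=sig,
        flip_rate=flip_rate,
    )
    return KOProfileMatrix(isolate_ids, ko_ids, mat), truth


#: planted cluster sizes for the collection-scale scenario: 126 isolates in
#: 15 gene-content clusters, sized after a cultured airway collection's
#: genus census with its large Streptococcus group split in two.
COLLECTION_CLUSTER_SIZES = (25, 24, 10, 9, 9, 8, 6, 6, 6, 5, 5, 4, 3, 3, 3)


def simulate_collection_ko_matrix(
    seed: int = 0,
    cluster_sizes: tuple[int, ...] = COLLECTION_CLUSTER_SIZES,
    n_kos: int = 5531,
    n_zero_variance: int = 254,
    n_duplicates: int = 2313,
    signature_size: int = 150,
    p_in: float = 0.98,
    p_out: float = 0.005,
) -> tuple[KOProfileMatrix, SyntheticTruth]:
    """Collection-scale KO matrix emulating a cultured isolate collection.

    The defaults reproduce the structure of a 126-isolate airway
    collection: ``n_kos`` total columns, of which ``n_zero_variance`` are
    constant (all-present or all-absent), ``n_duplicates`` are exact
    copies of other columns, and the remainder are distinct informative
    patterns.  Each planted cluster carries a block of ``signature_size``
    signature KOs present in its members with probability ``p_in`` and
    elsewhere with ``p_out``; remaining informative columns are 0.5
    background.  Distinctness of informative columns is enforced by
    redrawing collisions, so zero-variance filtering and duplicate
    collapse recover the planted counts exactly.
    """
    rng = rng_for(seed, "collection_ko_matrix")
    n_iso = int(sum(cluster_sizes))
    n_clusters = len(cluster_sizes)
    n_informative = n_kos - n_zero_variance - n_duplicates
    n_sig = n_clusters * signature_size
    if n_sig > n_informative:
        raise ValueError("signature blocks exceed the informative column budget")
    labels = np.repeat(np.arange(1, n_clusters + 1), cluster_sizes)

    cols = np.zeros((n_informative, n_iso), dtype=np.uint8)
    for c in range(n_clusters):
        block = slice(c * signature_size, (c + 1) * signature_size)
        inside = labels == c + 1
        p = np.where(inside, p_in, p_out)
        cols[block] = rng.random((signature_size, n_iso)) < p
    cols[n_sig:] = rng.random((n_informative - n_sig, n_iso)) < 0.5

    # enforce distinct, non-constant informative patterns
    for _ in range(100):
        seen: dict[bytes, int] = {}
        redo: list[int] = []
        for i in range(n_informative):
            s = cols[i].sum()
            key = cols[i].tobytes()
            if s == 0 or s == n_iso or key in seen:
                redo.append(i)
            else:
                seen[key] = i
        if not redo:
            break
        for i in redo:
            if i < n_sig:
                c = i // signature_size
                p = np.where(labels == c + 1, p_in, p_out)
                cols[i] = rng.random(n_iso) < p
            else:
                cols[i] = rng.random(n_iso) < 0.5
    else:  # pragma: no cover
        raise RuntimeError("could not generate distinct informative columns")

    dup_src = rng.integers(0, n_informative, size=n_duplicates)
    dup_cols = cols[dup_src]
    n_all_one = n_zero_variance // 2
    const_cols = np.concatenate([
        np.zeros((n_zero_variance - n_all_one, n_iso), dtype=np.uint8),
        np.ones((n_all_one, n_iso), dtype=np.uint8),
    ])
    full = np.concatenate([cols, dup_cols, const_cols], axis=0)
    order = rng.permutation(n_kos)
    full = full[order]
    ko_ids = [f"K{j + 1:05d}" for j in range(n_kos)]
    isolate_ids = [f"AW{i + 1:03d}" for i in range(n_iso)]
    # signature KO ids after shuffling
    inv = np.argsort(order)
    sig = {c + 1: [ko_ids[inv[i]] for i in range(c * signature_size, (c + 1) * signature_size)]
           for c in range(n_clusters)}
    truth = SyntheticTruth(
        seed=seed,
        cluster_labels=dict(zip(isolate_ids, labels.tolist())),
        signature_kos=sig,
        flip_rate=0.0,
        planted_counts={
            "n_isolates": n_iso,
            "n_kos": n_kos,
            "zero_variance": n_zero_variance,
            "duplicates": n_duplicates,
            "informative": n_kos - n_zero_variance,
            "distinct_informative": n_informative,
            "clusters": n_clusters,
        },
    )
    return KOProfileMatrix(isolate_ids, ko_ids, full.T), truth


# ---------------------------------------------------------------------------
# Dirichlet-multinomial mixtures

def simulate_dmm_counts(
    k: int,
    pi,
    alpha,
    n_samples: int,
    depth_law=("fixed", 1000),
    seed: int = 0,
    taxon_ids=None,
) -> tuple[CompositionCounts, SyntheticTruth]:
    """Sample counts from a k-component Dirichlet-multinomial mixture.

    Per sample: component ~ Categorical(pi); proportions ~
    Dirichlet(alpha_component); counts ~ Multinomial(depth, proportions),
    with depth drawn from ``depth_law`` = ("fixed", d) or
    ("loguniform", lo, hi).
    """
    pi = np.asarray(pi, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if len(pi) != k or not np.isclose(pi.sum(), 1.0) or (pi <= 0).any():
        raise ValueError("pi must be k positive weights summing to 1")
    if alpha.shape[0] != k or (alpha <= 0).any():
        raise ValueError("alpha must be a k x J positive matrix")
    rng = rng_for(seed, "dmm_counts")
    J = alpha.shape[1]
    comp = rng.choice(k, size=n_samples, p=pi)
    if depth_law[0] == "fixed":
        depths = np.full(n_samples, int(depth_law[1]))
    elif depth_law[0] == "loguniform":
        lo, hi = float(depth_law[1]), float(depth_law[2])
        depths = np.exp(rng.uniform(np.log(lo), np.log(hi), n_samples)).astype(int)
    else:
        raise ValueError(f"unknown depth law {depth_law[0]!r}")
    x = np.zeros((n_samples, J), dtype=np.int64)
    for s in range(n_samples):
        p = rng.dirichlet(alpha[comp[s]])
        x[s] = rng.multinomial(depths[s], p)
    sample_ids = [f"S{s + 1:04d}" for s in range(n_samples)]
    if taxon_ids is None:
        taxon_ids = [f"genus_{j + 1:02d}" for j in range(J)]
    truth = SyntheticTruth(seed=seed, dmm_pi=pi, dmm_alpha=alpha,
                           dmm_labels=comp + 1, depths=depths)
    return CompositionCounts(sample_ids, list(taxon_ids), x), truth


def airway_cohort_parameters(theta: float = 40.0) -> dict:
    """Generating parameters of the two-type airway cohort scenario.

    Two community types over 25 genus bins: type 1 dominated by
    Streptococcus, Veillonella and Prevotella, type 2 by Streptococcus,
    Veillonella and Haemophilus, with mixture weights matching per-type
    cohort sizes of 410 and 478 samples (888 total).  ``theta`` is the
    Dirichlet precision (sum of alpha), setting within-type
    overdispersion.
    """
    genera = [
        "Streptococcus", "Veillonella", "Prevotella", "Haemophilus",
        "Neisseria", "Gemella", "Rothia", "Pauljensenia", "Granulicatella",
        "Fusobacterium", "Leptotrichia", "Actinomyces", "Porphyromonas",
        "Alloprevotella", "Selenomonas", "Megasphaera", "Capnocytophaga",
        "Solobacterium", "Lachnoanaerobaculum", "Oribacterium",
        "Atopobium", "Campylobacter", "Tannerella", "Bergeyella", "Mycoplasma",
    ]
    J = len(genera)
    rest = np.full(J, 1.0)
    p1 = rest.copy()
    p1[[0, 1, 2, 3]] = [32.0, 18.0, 14.0, 2.0]       # Strep/Veillonella/Prevotella type
    p2 = rest.copy()
    p2[[0, 1, 2, 3]] = [26.0, 14.0, 2.0, 24.0]       # Strep/Veillonella/Haemophilus type
    p1 /= p1.sum()
    p2 /= p2.sum()
    return {
        "genera": genera,
        "pi": np.array([410 / 888, 478 / 888]),
        "alpha": np.vstack([p1, p2]) * theta,
    }


def simulate_airway_cohort(
    n_samples: int = 888, depth: int = 1000, seed: int = 0
) -> tuple[CompositionCounts, SyntheticTruth]:
    """Pooled two-type airway cohort at accession scale (genus-binned)."""
    pars = airway_cohort_parameters()
    return simulate_dmm_counts(
        2, pars["pi"], pars["alpha"], n_samples,
        depth_law=("fixed", depth), seed=seed, taxon_ids=pars["genera"],
    )


# ---------------------------------------------------------------------------
# contamination model

def simulate_contaminated_community(
    n_samples: int = 60,
    n_taxa: int = 30,
    biomass_range: float = 100.0,
    biomass_floor: float = 1e4,
    reads_per_copy: float = 0.05,
    contaminant_input: float = 500.0,
    base_theta: float = 20.0,
    seed: int = 0,
) -> tuple[OTUTable, pd.DataFrame, SyntheticTruth]:
    """Low-biomass community with one constant-input contaminant.

    Per sample, true biomass is log-uniform over a ``biomass_range``-fold
    gradient; the true community contributes Poisson reads proportional to
    biomass (``reads_per_copy``), distributed over ``n_taxa`` OTUs by a
    Dirichlet-multinomial, while the contaminant contributes Poisson reads
    with constant mean ``contaminant_input`` regardless of biomass.  Its
    relative abundance therefore falls as biomass rises — the signature
    the biomass-correlation contaminant rule detects.
    """
    if biomass_range <= 1:
        raise ValueError("biomass_range must exceed 1")
    if min(n_samples, n_taxa) < 2 or contaminant_input < 0:
        raise ValueError("invalid sizes or contaminant input")
    rng = rng_for(seed, "contaminated_community")
    biomass = np.exp(rng.uniform(np.log(biomass_floor),
                                 np.log(biomass_floor * biomass_range), n_samples))
    base_props = rng.dirichlet(np.full(n_taxa, 2.0))
    alpha = base_props * base_theta
    counts = np.zeros((n_samples, n_taxa + 1), dtype=np.int64)
    for s in range(n_samples):
        n_true = rng.poisson(reads_per_copy * biomass[s])
        p = rng.dirichlet(alpha)
        counts[s, :n_taxa] = rng.multinomial(n_true, p)
        counts[s, n_taxa] = rng.poisson(contaminant_input)
    otu_ids = [f"OTU_{j + 1:04d}" for j in range(n_taxa)] + ["OTU_contam"]
    sample_ids = [f"S{s + 1:03d}" for s in range(n_samples)]
    taxonomy = pd.DataFrame(
        {"kingdom": "Bacteria", "genus": [f"genus_{j % 12 + 1:02d}" for j in range(n_taxa)] + ["Reagenticola"]},
        index=otu_ids,
    )
    table = OTUTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids), taxonomy)
    meta = pd.DataFrame({
        "donor": [f"D{s // 2 + 1:03d}" for s in range(n_samples)],
        "study": "CELF",
        "site": ["ptOP", "LLL"] * (n_samples // 2) + ["ptOP"] * (n_samples % 2),
        "disease": "healthy",
        "sample_class": "sample",
        "biomass": biomass,
    }, index=sample_ids)
    truth = SyntheticTruth(seed=seed, contaminant_otus=["OTU_contam"],
                           contaminant_input=contaminant_input, biomass=biomass)
    return table, meta, truth


# ---------------------------------------------------------------------------
# sequences

_BASES = np.array(list("ACGT"))


def random_sequence(length: int = 250, seed: int = 0, seq_id: str = "seq") -> tuple[str, str]:
    """Uniform random DNA sequence as an (id, sequence) tuple."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = rng_for(seed, f"random_sequence:{seq_id}")
    return seq_id, "".join(rng.choice(_BASES, size=length))


def mutate_16s(seq: tuple[str, str], n_substitutions: int, seed: int = 0) -> tuple[str, str]:
    """Substitute exactly ``n_substitutions`` distinct positions to new bases."""
    sid, s = seq
    if n_substitutions < 0 or n_substitutions > len(s):
        raise ValueError("n_substitutions must lie in [0, len(seq)]")
    rng = rng_for(seed, f"mutate_16s:{sid}")
    positions = rng.choice(len(s), size=n_substitutions, replace=False)
    out = list(s)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return f"{sid}_mut{n_substitutions}", "".join(out)
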