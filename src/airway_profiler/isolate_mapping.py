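"""Mapping OTU representative 16S sequences onto isolate 16S genes.

Amplicon OTUs are linked to cultured isolates by pairwise percent
nucleotide identity between the OTU representative sequence and the 16S
rRNA genes extracted from isolate genome assemblies.  Identities are
binned into the three classes used to display OTU/isolate relationships
(95–97%, 97–99%, >=99%), and the binned hits form an OTU x isolate
"barcode" matrix: because many taxa carry several divergent 16S copies,
one OTU can hit many isolates and vice versa, and the combination of bins
along a row discriminates between closely related organisms (notably
streptococci) better than any single hit.

Alignment is a deterministic semi-global dynamic programme (end gaps
free), appropriate for comparing a ~250 nt amplicon fragment against a
full-length ~1.5 kb 16S gene; identity is computed over the aligned core
(matches / alignment columns, excluding terminal overhangs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "IdentityHit",
    "BIN_CODES",
    "read_fasta",
    "assign_bin",
    "pairwise_identity",
    "map_otus_to_isolates",
    "barcode_matrix",
]

#: identity-bin labels -> integer codes used in barcode matrices
BIN_CODES = {"95-97": 1, "97-99": 2, ">=99": 3}

_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class IdentityHit:
    """One OTU/isolate pairwise identity above threshold."""

    otu_id: str
    isolate_id: str
    percent_identity: float
    alignment_length: int
    bin: str


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercase sequence) tuples."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sequence ids in {path}")
    for sid, seq in records:
        if not seq:
            raise ValueError(f"empty sequence {sid!r}")
        bad = set(seq) - set(_ALPHABET)
        if bad:
            raise ValueError(f"sequence {sid!r} has invalid characters {sorted(bad)}")
    return records


def assign_bin(percent_identity: float) -> str | None:
    """Bin a percent identity: [95,97) -> '95-97', [97,99) -> '97-99', >=99 -> '>=99'."""
    if percent_identity >= 99.0:
        return ">=99"
    if percent_identity >= 97.0:
        return "97-99"
    if percent_identity >= 95.0:
        return "95-97"
    return None


def _make_aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    # N never counts as a match, including against another N (conservative)
    mat = substitution_matrices.Array(_ALPHABET, dims=2)
    for x in _ALPHABET:
        for y in _ALPHABET:
            mat[x, y] = match if (x == y and x != "N") else mismatch
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aligner.end_insertion_score = 0.0    # semi-global: free end gaps
    aligner.end_deletion_score = 0.0
    aligner.mode = "global"
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def pairwise_identity(
    a: tuple[str, str] | str,
    b: tuple[str, str] | str,
    aligner: PairwiseAligner | None = None,
) -> tuple[float, int]:
    """Percent identity and aligned-core length between two sequences.

    Sequences may be raw strings or (id, sequence) tuples.  The alignment
    is semi-global (terminal gaps free, so a short amplicon aligns inside
    a full-length gene without penalty); identity = matches / columns of
    the aligned core, where ambiguous N bases never count as matches.
    Deterministic: the first optimal alignment is used.
    """
    seq_a = a[1] if isinstance(a, tuple) else a
    seq_b = b[1] if isinstance(b, tuple) else b
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aln = (aligner or _DEFAULT_ALIGNER).align(seq_a.upper(), seq_b.upper())[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return 0.0, 0
    matches = 0
    columns = 0
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t_end is not None:
            columns += (ts - prev_t_end) + (qs - prev_q_end)  # internal gaps
        seg_t = seq_a[ts:te].upper()
        seg_q = seq_b[qs:qe].upper()
        matches += sum(1 for x, y in zip(seg_t, seg_q) if x == y and x != "N")
        columns += te - ts
        prev_t_end, prev_q_end = te, qe
    pid = 100.0 * matches / columns if columns else 0.0
    return pid, columns


def map_otus_to_isolates(
    otus,
    isolates16s,
    min_identity: float = 95.0,
    min_length: int = 206,
) -> list[IdentityHit]:
    """Score all OTU x isolate pairs and keep hits above thresholds.

    ``otus`` and ``isolates16s`` are FASTA paths or lists of (id, seq)
    tuples.  All surviving hits are kept — the OTU/isolate relationship is
    many-to-many by design, reflecting multi-copy 16S genes.  Hits with
    identity below ``min_identity`` (percent) or aligned core shorter than
    ``min_length`` columns are dropped.
    """
    if not 0 <= min_identity <= 100:
        raise ValueError("min_identity must lie in [0, 100]")
    if min_length < 1:
        raise ValueError("min_length must be positive")
    if isinstance(otus, (str, Path)):
        otus = read_fasta(otus)
    if isinstance(isolates16s, (str, Path)):
        isolates16s = read_fasta(isolates16s)
    hits: list[IdentityHit] = []
    for otu_id, otu_seq in otus:
        for iso_id, iso_seq in isolates16s:
            pid, ncols = pairwise_identity(otu_seq, iso_seq)
            if pid < min_identity or ncols < min_length:
                continue
            b = assign_bin(pid)
            if b is None:
                continue
            hits.append(IdentityHit(otu_id, iso_id, round(pid, 4), ncols, b))
    return hits


def barcode_matrix(hits: list[IdentityHit], otu_ids, isolate_ids) -> pd.DataFrame:
    """Dense OTU x isolate matrix of identity-bin codes.

    Codes: 0 = no hit, 1 = 95–97%, 2 = 97–99%, 3 = >=99%.  One pair maps
    to at most one cell; duplicate hits keep the best (highest) bin.
    """
    otu_ids, isolate_ids = list(otu_ids), list(isolate_ids)
    mat = pd.DataFrame(
        np.zeros((len(otu_ids), len(isolate_ids)), dtype=int),
        index=otu_ids, columns=isolate_ids,
    )
    for h in hits:
        if h.otu_id not in mat.index or h.isolate_id not in mat.columns:
            raise KeyError(f"hit references unknown id: {h.otu_id}/{h.isolate_id}")
        code = BIN_CODES[h.bin]
        if code > mat.at[h.otu_id, h.isolate_id]:
            mat.at[h.otu_id, h.isolate_id] = code
    return mat
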