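"""Catalytic-dyad conservation assessment.

Metacaspases, like caspases, depend on a cysteine-histidine catalytic dyad.
Each extracted metacaspase domain envelope is globally aligned to a reference
domain whose dyad positions are annotated; the envelope residues falling in
the two catalytic columns decide the conservation status: ``Positive`` iff
the cysteine column holds a C and the histidine column an H, ``Negative``
otherwise (a gap counts as substitution by deletion).

The aligner is a Needleman–Wunsch global alignment with a BLOSUM62 substitution
matrix and a linear gap penalty, with deterministic traceback (diagonal
preferred over up over left).  Only two column identities are ever consumed
from the alignment, which is why a pairwise reference-anchored alignment
suffices where a survey over real data would build a multiple alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .io_formats import AMINO_ACIDS

#: Default linear gap penalty (points subtracted per gap residue).
DEFAULT_GAP_PENALTY = 8

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = _BLOSUM62.alphabet


def _matrix_as_dict(matrix) -> dict[tuple[str, str], int]:
    return {
        (a, b): int(matrix[a, b])
        for a in matrix.alphabet
        for b in matrix.alphabet
    }


_BLOSUM62_DICT = _matrix_as_dict(_BLOSUM62)

_VALID_RESIDUES = AMINO_ACIDS | {"X"}


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment: two equal-length gapped strings and a score."""

    aligned_a: str
    aligned_b: str
    score: float

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.aligned_a, self.aligned_b)


@dataclass(frozen=True)
class DyadReference:
    """A reference metacaspase domain with annotated catalytic positions.

    ``cys_pos`` and ``his_pos`` are 1-based positions in ``reference_sequence``
    and must hold C and H respectively.
    """

    reference_sequence: str
    cys_pos: int
    his_pos: int

    def __post_init__(self) -> None:
        n = len(self.reference_sequence)
        if not (1 <= self.cys_pos <= n and 1 <= self.his_pos <= n):
            raise ValidationError("dyad positions outside reference sequence")
        if self.cys_pos == self.his_pos:
            raise ValidationError("cys_pos and his_pos must differ")
        if self.reference_sequence[self.cys_pos - 1] != "C":
            raise ValidationError(
                f"reference position {self.cys_pos} is "
                f"{self.reference_sequence[self.cys_pos - 1]!r}, expected 'C'"
            )
        if self.reference_sequence[self.his_pos - 1] != "H":
            raise ValidationError(
                f"reference position {self.his_pos} is "
                f"{self.reference_sequence[self.his_pos - 1]!r}, expected 'H'"
            )


@dataclass(frozen=True)
class DyadResult:
    """Conservation status of one sequence's catalytic dyad."""

    protein_id: str
    status: str  # "Positive" | "Negative"
    residue_at_cys: str  # one letter, or "-" for a deletion
    residue_at_his: str
    low_confidence: bool = False


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValidationError(f"{name}: empty sequence")
    bad = set(seq) - _VALID_RESIDUES
    if bad:
        raise ValidationError(f"{name}: non-amino-acid characters {sorted(bad)}")


def global_align(
    a: str,
    b: str,
    matrix: Mapping[tuple[str, str], int] | None = None,
    gap_penalty: int = DEFAULT_GAP_PENALTY,
) -> Alignment:
    """Optimal Needleman–Wunsch global alignment of two protein sequences.

    Linear gap penalty; ties broken deterministically by preferring the
    diagonal move, then the vertical (gap in ``b``), then the horizontal
    (gap in ``a``).
    """
    _check_sequence(a, "sequence a")
    _check_sequence(b, "sequence b")
    sub = _BLOSUM62_DICT if matrix is None else matrix
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    # pointers: 0 = diagonal, 1 = up (consume a), 2 = left (consume b)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    score[:, 0] = -gap_penalty * np.arange(n + 1)
    score[0, :] = -gap_penalty * np.arange(m + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        row_prev = score[i - 1]
        row = score[i]
        for j in range(1, m + 1):
            diag = row_prev[j - 1] + sub[(ai, b[j - 1])]
            up = row_prev[j] - gap_penalty
            left = row[j - 1] - gap_penalty
            if diag >= up and diag >= left:
                row[j] = diag
                # ptr stays 0
            elif up >= left:
                row[j] = up
                ptr[i, j] = 1
            else:
                row[j] = left
                ptr[i, j] = 2
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif move == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m]))


def classify_dyad(
    envelope_sequence: str, ref: DyadReference, protein_id: str = ""
) -> DyadResult:
    """Decide dyad conservation of one domain envelope against the reference.

    The envelope is aligned to the reference; the envelope residues in the
    columns holding the reference's catalytic cysteine and histidine decide
    the status.  Both catalytic columns being deletions (e.g. a terminal
    fragment that never reaches them) marks the call low-confidence: the
    alignment carries no signal at either catalytic position.
    """
    aln = global_align(ref.reference_sequence, envelope_sequence)
    residues: dict[int, str] = {}
    ref_pos = 0
    for ra, rb in aln.columns():
        if ra != "-":
            ref_pos += 1
            if ref_pos in (ref.cys_pos, ref.his_pos):
                residues[ref_pos] = rb
    at_cys = residues[ref.cys_pos]
    at_his = residues[ref.his_pos]
    status = "Positive" if (at_cys == "C" and at_his == "H") else "Negative"
    low_confidence = at_cys == "-" and at_his == "-"
    return DyadResult(protein_id, status, at_cys, at_his, low_confidence)


def substitution_profile(
    results: Sequence[DyadResult], groups: Mapping[str, str]
) -> dict:
    """Summarize dyad conservation per taxonomic group and the substitutions seen.

    Returns a dict with a ``per_group`` table (group, n, n_positive,
    fraction_positive) and, over all Negative results, the distribution of
    residues replacing the catalytic C (``cys_substitutions``) and H
    (``his_substitutions``) as residue -> (count, fraction of substitutions).
    """
    rows = []
    by_group: dict[str, list[DyadResult]] = {}
    for r in results:
        by_group.setdefault(groups[r.protein_id], []).append(r)
    for group in sorted(by_group):
        members = by_group[group]
        n_pos = sum(1 for r in members if r.status == "Positive")
        rows.append(
            {
                "group": group,
                "n": len(members),
                "n_positive": n_pos,
                "fraction_positive": n_pos / len(members),
            }
        )
    cys_subs = Counter(
        r.residue_at_cys
        for r in results
        if r.status == "Negative" and r.residue_at_cys != "C"
    )
    his_subs = Counter(
        r.residue_at_his
        for r in results
        if r.status == "Negative" and r.residue_at_his != "H"
    )

    def _dist(counter: Counter) -> dict[str, tuple[int, float]]:
        total = sum(counter.values())
        return {
            res: (count, count / total) for res, count in sorted(counter.items())
        }

    return {
        "per_group": pd.DataFrame(
            rows, columns=["group", "n", "n_positive", "fraction_positive"]
        ),
        "cys_substitutions": _dist(cys_subs),
        "his_substitutions": _dist(his_subs),
    }


def load_reference(path: str | Path, cys_pos: int | None = None, his_pos: int | None = None) -> DyadReference:
    """Load a dyad reference from FASTA.

    Dyad positions may be given explicitly or embedded in the header
    description as ``cys=<pos> his=<pos>`` tokens.
    """
    rec = next(SeqIO.parse(str(path), "fasta"), None)
    if rec is None:
        raise ValidationError(f"{path}: no FASTA record")
    tokens = dict(
        t.split("=", 1) for t in rec.description.split() if "=" in t
    )
    if cys_pos is None:
        if "cys" not in tokens:
            raise ValidationError(f"{path}: cys position neither given nor in header")
        cys_pos = int(tokens["cys"])
    if his_pos is None:
        if "his" not in tokens:
            raise ValidationError(f"{path}: his position neither given nor in header")
        his_pos = int(tokens["his"])
    return DyadReference(str(rec.seq).upper(), cys_pos=cys_pos, his_pos=his_pos)


def load_default_reference() -> DyadReference:
    """Load the bundled synthetic reference domain.

    The bundled sequence is a synthetic 252-residue metacaspase-like domain
    with annotated dyad positions (his=90, cys=150), intended for testing and
    simulation; surveys over real data should supply a curated reference.
    """
    with resources.as_file(
        resources.files("mcsurvey").joinpath("data/synthetic_reference_domain.fasta")
    ) as p:
        return load_reference(p)
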