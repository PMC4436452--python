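"""Conjoint-triad featurization of domain sequences.

Each amino acid is mapped to one of six physicochemical classes, so a
3-residue window takes one of 6^3 = 216 triad types. A domain sequence is
encoded as the frequency vector of its triad types over all valid windows,
which places every instance vector on the 216-simplex.

The exact 6-class partition behind the published 216-dimensional encoding
is not standardized; the default here is a Dayhoff-style grouping
({C}, {A,G,P,S,T}, {D,E,N,Q}, {H,K,R}, {I,L,M,V}, {F,W,Y}) and any other
partition of the 20 standard residues into 6 classes may be supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .datamodel import Bag, DomainInstance

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

# residues with no class: windows containing them are skipped, not fatal
AMBIGUITY_CODES = set("BJOUXZ*")

DEFAULT_GROUPS = (
    "C",
    "AGPST",
    "DENQ",
    "HKR",
    "ILMV",
    "FWY",
)

N_CLASSES = 6
N_TRIADS = N_CLASSES**3  # 216


@dataclass(frozen=True)
class TriadAlphabet:
    """Partition of the 20 standard amino acids into 6 classes."""

    groups: tuple

    def __init__(self, groups=DEFAULT_GROUPS):
        groups = tuple("".join(sorted(g)) for g in groups)
        if len(groups) != N_CLASSES:
            raise ValueError(f"need exactly {N_CLASSES} classes, got {len(groups)}")
        covered = "".join(groups)
        if len(set(covered)) != len(covered):
            raise ValueError("classes are not disjoint")
        if set(covered) != STANDARD_RESIDUES:
            raise ValueError("classes must cover exactly the 20 standard residues")
        object.__setattr__(self, "groups", groups)

    @property
    def index(self) -> dict:
        return {res: c for c, group in enumerate(self.groups) for res in group}

    @classmethod
    def from_config(cls, path) -> "TriadAlphabet":
        """Load a residue -> class-id map from a JSON config file."""
        with open(path) as fh:
            mapping = json.load(fh)
        groups = [[] for _ in range(N_CLASSES)]
        for res, cid in mapping.items():
            groups[int(cid)].append(res.upper())
        return cls(tuple("".join(g) for g in groups))


def encode_triads(sequence: str, alphabet: TriadAlphabet | None = None) -> np.ndarray:
    """Encode a sequence as its 216-dim triad-frequency vector.

    A length-3 window is valid iff all three residues map to a class;
    windows broken by ambiguity codes are skipped. Counts are normalized by
    the number of valid windows, so the output sums to 1.

    Raises ValueError when no valid window exists.
    """
    if alphabet is None:
        alphabet = TriadAlphabet()
    index = alphabet.index
    seq = sequence.upper()
    counts = np.zeros(N_TRIADS, dtype=float)
    n_valid = 0
    for i in range(len(seq) - 2):
        try:
            c1, c2, c3 = index[seq[i]], index[seq[i + 1]], index[seq[i + 2]]
        except KeyError:
            continue
        counts[36 * c1 + 6 * c2 + c3] += 1
        n_valid += 1
    if n_valid == 0:
        raise ValueError(f"no valid triad window in sequence {sequence!r}")
    return counts / n_valid


def featurize_protein(
    domains: list, alphabet: TriadAlphabet | None = None
) -> Bag:
    """Turn a protein's ranked domain list into a bag of triad vectors."""
    if not domains:
        raise ValueError("protein has no domains")
    protein_ids = {d.protein_id for d in domains}
    if len(protein_ids) != 1:
        raise ValueError(f"domains from multiple proteins: {sorted(protein_ids)}")
    ordered = sorted(domains, key=lambda d: d.rank)
    vectors = []
    for dom in ordered:
        try:
            vectors.append(encode_triads(dom.sequence, alphabet))
        except ValueError as exc:
            raise ValueError(
                f"protein {dom.protein_id}, domain rank {dom.rank}: {exc}"
            ) from exc
    return Bag(ordered[0].protein_id, np.vstack(vectors))


def featurize_all(
    domains: list, alphabet: TriadAlphabet | None = None
) -> list:
    """Group a flat DomainInstance list by protein and featurize each one."""
    by_protein: dict = {}
    for d in domains:
        by_protein.setdefault(d.protein_id, []).append(d)
    return [featurize_protein(doms, alphabet) for doms in by_protein.values()]
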