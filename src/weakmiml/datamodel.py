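"""Core data types for multi-instance multi-label (MIML) protein function data.

A protein is a *bag* of instances, one 216-dimensional conjoint-triad
frequency vector per conserved domain. Its functions are a set of Gene
Ontology (GO) molecular-function terms, encoded as one row of a binary
bag-by-label matrix. Three matrix roles are distinguished:

``full``      the complete ground-truth annotation Y
``observed``  a weakly labelled matrix with only a subset of true
              positives retained (observed 0 means *unknown*, not negative)
``corrected`` a learner-completed matrix constrained to contain the
              observed positives

This module also holds the readers for the plain-text formats the pipeline
consumes (FASTA, TSV domain tables, TSV annotation tables, OBO ontology
subsets) and the JSON dataset serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
from Bio import SeqIO

GO_MF_ROOT = "GO:0003674"

SCHEMA_VERSION = 1

VALID_ROLES = ("full", "observed", "corrected")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class DomainInstance:
    """One conserved domain of a protein, pre-featurization.

    ``rank`` is the 1-based order of the domain within its protein.
    """

    protein_id: str
    rank: int
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(
                f"empty domain sequence for {self.protein_id} rank {self.rank}"
            )
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")


@dataclass
class Bag:
    """A protein as an ordered list of fixed-dimension instance vectors."""

    bag_id: str
    instances: np.ndarray  # shape (n_i, dim)

    def __post_init__(self):
        arr = np.asarray(self.instances, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError(
                f"bag {self.bag_id!r}: instances must be a non-empty 2-D array"
            )
        self.instances = arr

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]

    @property
    def dim(self) -> int:
        return self.instances.shape[1]

    def __eq__(self, other):
        if not isinstance(other, Bag):
            return NotImplemented
        return self.bag_id == other.bag_id and np.array_equal(
            self.instances, other.instances
        )


@dataclass(frozen=True)
class LabelSpace:
    """Ordered list of unique GO term identifiers (canonical = sorted)."""

    terms: tuple

    def __init__(self, terms: Iterable[str]):
        terms = tuple(terms)
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate terms in label space")
        if list(terms) != sorted(terms):
            raise ValueError("label space must be lexicographically sorted")
        object.__setattr__(self, "terms", terms)

    def __len__(self) -> int:
        return len(self.terms)

    def index(self, term: str) -> int:
        return self.terms.index(term)


@dataclass
class LabelMatrix:
    """Binary bag-by-label matrix with an explicit role."""

    values: np.ndarray
    role: str

    def __post_init__(self):
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {VALID_ROLES}, got {self.role!r}")
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError("label matrix must be 2-D")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("label matrix entries must be 0/1")
        self.values = arr.astype(np.int8)

    @property
    def shape(self):
        return self.values.shape

    def __eq__(self, other):
        if not isinstance(other, LabelMatrix):
            return NotImplemented
        return self.role == other.role and np.array_equal(self.values, other.values)


def check_weak_consistency(observed: LabelMatrix, full: LabelMatrix) -> None:
    """Assert the weak-label contract: observed positives ⊆ true positives."""
    if observed.shape != full.shape:
        raise ValueError("shape mismatch between observed and full matrices")
    if np.any(observed.values > full.values):
        raise ValueError("observed matrix is not elementwise <= full matrix")


@dataclass
class MIMLDataset:
    """Bags plus their label matrix over a shared label space."""

    bags: list
    labels: LabelMatrix
    label_space: LabelSpace

    def __post_init__(self):
        m = len(self.bags)
        if m == 0:
            raise ValueError("dataset must contain at least one bag")
        if self.labels.shape != (m, len(self.label_space)):
            raise ValueError(
                f"label matrix shape {self.labels.shape} does not match "
                f"{m} bags x {len(self.label_space)} labels"
            )
        ids = [b.bag_id for b in self.bags]
        if len(set(ids)) != len(ids):
            raise ValueError("bag_ids are not unique")
        if self.labels.role == "full" and self.labels.values.size:
            empty = np.flatnonzero(self.labels.values.sum(axis=0) == 0)
            if empty.size:
                bad = [self.label_space.terms[i] for i in empty]
                raise ValueError(f"full label matrix has empty columns: {bad}")

    @property
    def n_bags(self) -> int:
        return len(self.bags)

    @property
    def n_labels(self) -> int:
        return len(self.label_space)

    def __eq__(self, other):
        if not isinstance(other, MIMLDataset):
            return NotImplemented
        return (
            self.bags == other.bags
            and self.labels == other.labels
            and self.label_space == other.label_space
        )


@dataclass
class GODag:
    """is_a DAG over GO molecular-function terms, rooted at GO:0003674."""

    graph: nx.DiGraph  # edges child -> parent
    root: str = GO_MF_ROOT

    def __post_init__(self):
        if self.root not in self.graph:
            self.graph.add_node(self.root)
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"GO graph contains a cycle: {cycle}")
        for node in self.graph.nodes:
            if node == self.root:
                continue
            if not nx.has_path(self.graph, node, self.root):
                raise ValueError(f"term {node} has no is_a path to the root")

    @property
    def nodes(self):
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set:
        """All is_a ancestors of ``term`` (descendants in the child->parent graph)."""
        if term not in self.graph:
            raise KeyError(f"unknown GO term: {term}")
        return set(nx.descendants(self.graph, term))


# ---------------------------------------------------------------------------
# readers


def read_fasta(path) -> list:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    Ids are the first whitespace-delimited token after '>'; sequences are
    uppercased with line breaks removed.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"{path}: record with empty id")
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    return records


def read_domain_table(path) -> list:
    """Read a TSV of per-protein domain sequences into DomainInstance rows.

    Requires header columns protein_id, rank, sequence. Rows are grouped per
    protein and sorted by rank; duplicate (protein_id, rank) is an error.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "sequence": str})
    required = {"protein_id", "rank", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(subset=["protein_id", "rank"]).any():
        dup = df[df.duplicated(subset=["protein_id", "rank"], keep=False)]
        key = dup.iloc[0]
        raise ParseError(
            f"{path}: duplicate (protein_id, rank) = "
            f"({key['protein_id']}, {key['rank']})"
        )
    # stable sort keeps protein blocks in first-appearance order
    order = {pid: i for i, pid in enumerate(dict.fromkeys(df["protein_id"]))}
    df = df.sort_values(
        ["protein_id", "rank"],
        key=lambda col: col.map(order) if col.name == "protein_id" else col,
        kind="stable",
    )
    return [
        DomainInstance(str(r.protein_id), int(r.rank), str(r.sequence).upper())
        for r in df.itertuples()
    ]


def read_annotation_table(path) -> dict:
    """Read a TSV of protein_id -> semicolon-separated GO ids."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "go_terms"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for r in df.itertuples():
        terms = set()
        cell = r.go_terms
        if isinstance(cell, str) and cell.strip():
            terms = {t.strip() for t in cell.split(";") if t.strip()}
        out[str(r.protein_id)] = terms
    return out


def parse_obo_subset(path) -> GODag:
    """Parse an OBO 1.2 file, keeping molecular_function terms only.

    Obsolete terms are dropped; acyclicity and rootedness are verified.
    An is_a edge referencing a term outside the retained set is an error.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    # obonet edges run child -> parent keyed by relation type
    mf_nodes = {
        n
        for n, data in graph.nodes(data=True)
        if data.get("namespace") == "molecular_function"
    }
    dag = nx.DiGraph()
    dag.add_nodes_from(mf_nodes)
    dag.add_node(GO_MF_ROOT)
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a" or child not in mf_nodes:
            continue
        if parent not in mf_nodes and parent != GO_MF_ROOT:
            raise ParseError(
                f"{path}: term {child} has is_a to unknown/non-MF id {parent}"
            )
        dag.add_edge(child, parent)
    return GODag(dag)


# ---------------------------------------------------------------------------
# label construction


def propagate_annotations(direct_terms: Iterable[str], dag: GODag) -> set:
    """True-path closure: direct terms plus all is_a ancestors, root excluded."""
    direct = set(direct_terms)
    out = set()
    for term in direct:
        if term not in dag.graph:
            raise KeyError(f"unknown GO term: {term}")
        out.add(term)
        out |= dag.ancestors(term)
    out.discard(dag.root)
    return out


def build_dataset(
    bags: Sequence[Bag],
    annotations: Mapping[str, Iterable[str]],
    label_space: LabelSpace | None = None,
    role: str = "full",
) -> MIMLDataset:
    """Assemble bags and per-bag GO term sets into a MIMLDataset.

    When ``label_space`` is omitted it is the sorted union of observed terms;
    for a full matrix, columns with zero positives are dropped. Row order
    follows bag input order.
    """
    ids = [b.bag_id for b in bags]
    unknown = set(annotations) - set(ids)
    if unknown:
        raise ValueError(f"annotations reference unknown bag_ids: {sorted(unknown)}")
    missing = set(ids) - set(annotations)
    if missing:
        raise ValueError(f"bags without annotation entry: {sorted(missing)}")

    if label_space is None:
        all_terms = sorted(set().union(*(set(annotations[i]) for i in ids)))
        if not all_terms:
            raise ValueError("no labels: every annotation set is empty")
        label_space = LabelSpace(all_terms)

    L = len(label_space)
    idx = {t: j for j, t in enumerate(label_space.terms)}
    values = np.zeros((len(bags), L), dtype=np.int8)
    for i, bag_id in enumerate(ids):
        for term in annotations[bag_id]:
            if term not in idx:
                raise ValueError(f"term {term} not in explicit label space")
            values[i, idx[term]] = 1

    if role == "full":
        keep = values.sum(axis=0) > 0
        if not keep.all():
            values = values[:, keep]
            label_space = LabelSpace(
                [t for t, k in zip(label_space.terms, keep) if k]
            )
        if values.shape[1] == 0:
            raise ValueError("no labels: every annotation set is empty")

    return MIMLDataset(list(bags), LabelMatrix(values, role), label_space)


# ---------------------------------------------------------------------------
# serialization


def save_dataset(dataset: MIMLDataset, path) -> None:
    """Write a dataset as a single JSON document with an explicit schema version."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "label_space": list(dataset.label_space.terms),
        "bags": [
            {"bag_id": b.bag_id, "instances": b.instances.tolist()}
            for b in dataset.bags
        ],
        "labels": {
            "role": dataset.labels.role,
            "values": dataset.labels.values.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_dataset(path) -> MIMLDataset:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ParseError(
            f"{path}: schema_version {version!r} != supported {SCHEMA_VERSION}"
        )
    bags = [
        Bag(b["bag_id"], np.asarray(b["instances"], dtype=float))
        for b in doc["bags"]
    ]
    labels = LabelMatrix(
        np.asarray(doc["labels"]["values"]), doc["labels"]["role"]
    )
    return MIMLDataset(bags, labels, LabelSpace(doc["label_space"]))
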