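"""File formats: gene-order tables, distance matrices, Newick, YAML config.

Gene-order tables are TSV with one taxon per row::

    # comment lines start with '#'
    Homo_sapiens<TAB>cox1 cox2 atp8 atp6 cox3 nad3 nad4L nad4 nad5 -nad6 cob rrnS rrnL nad1 nad2

Newick output labels hypothetical ancestors ``HTU#k`` and keeps OTU names on
internal nodes where the inference places an observed gene order at an
ancestral position; every branch has unit length (one rearrangement).
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import yaml

from .distmatrix import DistanceMatrix
from .genome import Genome, GenomeError, parse_genome
from .treesearch import HTU_PREFIX, PPH, PhyloTree, is_htu

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_matrix",
    "write_matrix",
    "write_newick",
    "read_newick",
    "read_pph_config",
    "example_data",
]

logger = logging.getLogger("mitorder")


def _looks_numeric(label: str) -> bool:
    return label.isdigit()


def read_dataset(path, merge_duplicates: bool = True) -> list[tuple[str, Genome]]:
    """Ordered ``(taxon, genome)`` dataset from a gene-order TSV.

    Duplicate taxon names and mixed gene alphabets (integer labels in one
    row, gene names in another) are rejected.  Taxa whose gene order equals
    an earlier taxon's are dropped with a logged mapping when
    ``merge_duplicates`` is set.
    """
    rows: list[tuple[str, Genome]] = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" not in line:
            raise GenomeError(f"{path}:{ln}: expected 'taxon<TAB>tokens'")
        name, tokens = line.split("\t", 1)
        name = name.strip()
        if not name:
            raise GenomeError(f"{path}:{ln}: empty taxon name")
        rows.append((name, parse_genome(tokens)))
    if not rows:
        raise GenomeError(f"{path}: empty dataset")
    names = [n for n, _ in rows]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise GenomeError(f"{path}: duplicate taxon names: {dup}")
    numeric = {_looks_numeric(lab) for _, g in rows for lab in g.labels}
    if len(numeric) > 1:
        raise GenomeError(f"{path}: mixed integer and name gene alphabets")
    if not merge_duplicates:
        return rows
    kept: list[tuple[str, Genome]] = []
    for name, g in rows:
        rep = next((kn for kn, kg in kept if kg.gene_set == g.gene_set and kg == g), None)
        if rep is None:
            kept.append((name, g))
        else:
            logger.warning("%s: %r duplicates the gene order of %r; merged", path, name, rep)
    return kept


def write_dataset(dataset, path) -> None:
    with open(path, "w") as fh:
        for name, g in dataset:
            fh.write(f"{name}\t{g}\n")


def write_matrix(matrix: DistanceMatrix, path) -> None:
    """TSV matrix with a JSON sidecar carrying cell status and removals."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(matrix.taxa) + "\n")
        for i, t in enumerate(matrix.taxa):
            fh.write(t + "\t" + "\t".join(str(int(v)) for v in matrix.values[i]) + "\n")
    side = {
        "k_max": matrix.k_max,
        "lower_bound_cells": [
            [matrix.taxa[i], matrix.taxa[j]]
            for i in range(len(matrix.taxa))
            for j in range(i + 1, len(matrix.taxa))
            if not matrix.exact[i, j]
        ],
        "removals": {
            f"{a}|{b}": {"from_a": list(ra), "from_b": list(rb)}
            for (a, b), (ra, rb) in matrix.removals.items()
        },
        "merged": matrix.merged,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=2))


def read_matrix(path) -> DistanceMatrix:
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    taxa = tuple(lines[0].split("\t")[1:])
    values = np.array(
        [[int(x) for x in line.split("\t")[1:]] for line in lines[1:]], dtype=int
    )
    exact = np.ones_like(values, dtype=bool)
    k_max = int(values.max()) if values.size else 8
    removals = {}
    merged = {}
    side_path = path.with_suffix(path.suffix + ".json")
    if side_path.exists():
        side = json.loads(side_path.read_text())
        k_max = side.get("k_max", k_max)
        for a, b in side.get("lower_bound_cells", []):
            i, j = taxa.index(a), taxa.index(b)
            exact[i, j] = exact[j, i] = False
        for key, rem in side.get("removals", {}).items():
            a, b = key.split("|")
            removals[(a, b)] = (tuple(rem["from_a"]), tuple(rem["from_b"]))
        merged = side.get("merged", {})
    return DistanceMatrix(taxa, values, exact, k_max, removals, merged)


# -- trees ----------------------------------------------------------------


def write_newick(tree: PhyloTree, assignment=None, path=None, root: str | None = None) -> str:
    """Serialize a tree to Newick (unit branch lengths, ``HTU#k`` labels).

    With an ancestral assignment, a sidecar TSV ``<path>.htus.tsv`` lists
    each ancestor's candidate gene orders (one row per candidate).
    """
    nwk = tree.newick(root=root)
    if path is not None:
        Path(path).write_text(nwk + "\n")
        if assignment is not None:
            side = Path(str(path) + ".htus.tsv")
            with open(side, "w") as fh:
                for h in sorted(assignment.candidates):
                    for g in assignment.candidates[h]:
                        fh.write(f"{h}\t{g}\n")
    return nwk


def read_newick(path_or_text) -> PhyloTree:
    """Parse a Newick file (or string) back into a tree; unlabeled internal
    nodes become fresh HTUs."""
    text = str(path_or_text)
    if not text.strip().endswith(";"):
        text = Path(path_or_text).read_text()
    dt = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=False)
    counter = [0]
    names: dict[int, str] = {}

    def name_of(node) -> str:
        key = id(node)
        if key not in names:
            label = None
            if node.taxon is not None and node.taxon.label:
                label = node.taxon.label
            elif node.label:
                label = node.label
            if label is None:
                counter[0] += 1
                label = f"{HTU_PREFIX}fresh{counter[0]}"
            names[key] = label.replace(" ", "_")
        return names[key]

    edges = set()
    for node in dt.preorder_node_iter():
        for child in node.child_nodes():
            edges.add(frozenset((name_of(node), name_of(child))))
    nodes = tuple(sorted({x for e in edges for x in e}))
    # renumber fresh HTUs consecutively
    ren = {}
    for x in nodes:
        if x.startswith(f"{HTU_PREFIX}fresh"):
            ren[x] = f"{HTU_PREFIX}{len(ren) + 1000}"
    if ren:
        nodes = tuple(sorted(ren.get(x, x) for x in nodes))
        edges = {frozenset(ren.get(x, x) for x in e) for e in edges}
    return PhyloTree(nodes, frozenset(edges))


# -- configuration --------------------------------------------------------


def read_pph_config(path) -> tuple[list[PPH], str | None]:
    """YAML config: ``pphs: {name: [taxa...]}`` plus optional ``root``."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    pphs = [
        PPH(name, frozenset(taxa)) for name, taxa in (cfg.get("pphs") or {}).items()
    ]
    return pphs, cfg.get("root")


def example_data(name: str) -> Path:
    """Path to a packaged example file (e.g. ``human_mtdna.tsv``)."""
    return Path(str(resources.files("mitorder").joinpath("data", name)))
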