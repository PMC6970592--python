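"""Reading and writing: per-specimen volume tables, Newick trees, results.

The volume table is a CSV/TSV with one row per hemithorax: species, sex,
specimen id, and raw volumes (mm^3) of the seven measured muscles (hg1-4,
the first basalare b1, and the dorsal/ventral tergopleural muscles d-Tp and
v-Tp).  Rows with missing or nonpositive volumes are retained but flagged
incomplete, never silently dropped.  Newick parsing and serialization are
delegated to dendropy.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .phylo import Node, PhyloTree

logger = logging.getLogger(__name__)

MUSCLES = ("hg1", "hg2", "hg3", "hg4", "b1", "d-Tp", "v-Tp")
HG_MUSCLES = ("hg1", "hg2", "hg3", "hg4")

SEX_ALIASES = {"m": "male", "male": "male", "males": "male",
               "f": "female", "female": "female", "females": "female"}


def canonical_muscle(name: str) -> Optional[str]:
    """Map header spellings (dTp, d_Tp, D-TP, ...) to canonical muscle names."""
    key = re.sub(r"[\s_\-]", "", name).lower()
    table = {re.sub(r"[\s_\-]", "", m).lower(): m for m in MUSCLES}
    return table.get(key)


@dataclass
class VolumeRecord:
    """One hemithorax: raw volumes (mm^3) of the seven measured muscles."""

    species: str
    sex: str
    specimen_id: str
    volumes: dict
    complete: bool = True
    note: str = ""


@dataclass
class VolumeTable:
    records: list[VolumeRecord]
    provenance: str = ""

    def complete_records(self) -> list[VolumeRecord]:
        return [r for r in self.records if r.complete]

    def species(self) -> list[str]:
        return sorted({r.species for r in self.complete_records()})

    def single_sex_species(self) -> list[str]:
        """Species represented by only one sex (unclassifiable downstream)."""
        sexes: dict[str, set] = {}
        for r in self.complete_records():
            sexes.setdefault(r.species, set()).add(r.sex)
        return sorted(s for s, v in sexes.items() if len(v) < 2)

    def validate(self) -> None:
        keys = [(r.species, r.sex, r.specimen_id) for r in self.records]
        if len(set(keys)) != len(keys):
            dups = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (species, sex, specimen) keys: {dups[:5]}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({"species": r.species, "sex": r.sex,
                         "specimen_id": r.specimen_id,
                         **{m: r.volumes.get(m) for m in MUSCLES},
                         "complete": r.complete})
        return pd.DataFrame(rows)


def read_volume_table(path, *, dialect: Optional[str] = None,
                      column_map: Optional[Mapping[str, str]] = None) -> VolumeTable:
    """Read a volume table; never drops rows (kept + flagged = input rows).

    ``dialect`` is ``"csv"`` or ``"tsv"`` (inferred from the suffix when
    omitted).  ``column_map`` renames non-standard headers to the expected
    ones (species, sex, specimen_id, and the seven muscle names, any
    spelling accepted for the latter).  Unparseable or nonpositive numeric
    cells flag the record as incomplete; a missing required column is fatal.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}[dialect] if dialect else \
        ("," if path.suffix.lower() == ".csv" else "\t")
    df = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    rename = {}
    for col in df.columns:
        m = canonical_muscle(str(col))
        if m:
            rename[col] = m
    df = df.rename(columns=rename)

    required = ["species", "sex", "specimen_id", *MUSCLES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"volume table {path} is missing required "
                         f"column(s): {missing}")

    records: list[VolumeRecord] = []
    for _, row in df.iterrows():
        sex_raw = str(row["sex"]).strip().lower()
        sex = SEX_ALIASES.get(sex_raw)
        vols, notes = {}, []
        for m in MUSCLES:
            try:
                v = float(row[m])
            except (TypeError, ValueError):
                notes.append(f"{m} unparseable")
                continue
            if not v > 0 or v != v:
                notes.append(f"{m} nonpositive")
                continue
            vols[m] = v
        if sex is None:
            notes.append(f"sex label {row['sex']!r} unrecognized")
            sex = sex_raw
        complete = len(vols) == len(MUSCLES) and not notes
        records.append(VolumeRecord(
            species=str(row["species"]).strip(), sex=sex,
            specimen_id=str(row["specimen_id"]).strip(),
            volumes=vols, complete=complete, note="; ".join(notes)))

    table = VolumeTable(records=records, provenance=str(path))
    table.validate()
    counts = {}
    for r in records:
        key = (r.species, r.sex)
        kept, flagged = counts.get(key, (0, 0))
        counts[key] = (kept + r.complete, flagged + (not r.complete))
    for (sp, sex), (kept, flagged) in sorted(counts.items()):
        logger.info("loaded %s/%s: %d kept, %d flagged", sp, sex, kept, flagged)
    single = table.single_sex_species()
    if single:
        logger.warning("single-sex species (unclassifiable): %s", single)
    return table


def write_volume_table(table: VolumeTable, path) -> None:
    df = table.to_frame().drop(columns=["complete"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# -- Newick -------------------------------------------------------------------

def _check_balanced(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(
                    f"unbalanced ')' at character offset {offset}")
    if depth != 0:
        raise ValueError(f"unbalanced '(': {depth} unclosed at end of input")


def _from_dendropy(dtree: dendropy.Tree,
                   default_length: Optional[float]) -> PhyloTree:
    counter = [0]

    def build(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length
        node = Node(counter[0], label=label, length=length)
        counter[0] += 1
        for child in dnode.child_nodes():
            node.add_child(build(child))
        return node

    root = build(dtree.seed_node)
    root.length = None
    tree = PhyloTree(root)
    for node in tree.postorder():
        if node is tree.root or node.length is not None:
            continue
        if default_length is None:
            raise ValueError(
                f"branch above node {node.label or node.id} has no length; "
                "supply default_length to proceed")
        node.length = default_length
    return tree


def read_newick(path, *, default_length: Optional[float] = None) -> PhyloTree:
    """Read one rooted Newick tree (quoted labels, internal labels and
    polytomies supported).  Missing branch lengths are an error unless a
    ``default_length`` is supplied."""
    text = Path(path).read_text().strip()
    return parse_newick(text, default_length=default_length)


def parse_newick(text: str, *,
                 default_length: Optional[float] = None) -> PhyloTree:
    if not text.strip():
        raise ValueError("empty Newick string")
    _check_balanced(text)
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    return _from_dendropy(dtree, default_length)


def _to_dendropy(tree: PhyloTree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: Node, dnode) -> None:
        for child in node.children:
            dchild = dnode.new_child()
            dchild.edge.length = child.length
            if child.is_leaf:
                dchild.taxon = taxa.require_taxon(label=child.label)
            elif child.label:
                dchild.label = child.label
            build(child, dchild)

    build(tree.root, dtree.seed_node)
    if tree.root.label:
        dtree.seed_node.label = tree.root.label
    return dtree


def write_newick(tree: PhyloTree, path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def newick_string(tree: PhyloTree) -> str:
    return _to_dendropy(tree).as_string(
        schema="newick", suppress_rooting=True,
        unquoted_underscores=True).strip()


# -- results ------------------------------------------------------------------

FLOAT_FMT = "%.6f"


def write_results(outdir, *, effects_frame: pd.DataFrame,
                  asr_frames: Mapping[str, pd.DataFrame],
                  manifest: Mapping) -> dict[str, Path]:
    """Write the standard result bundle: effects TSV, one per-node
    probability TSV per muscle, and a JSON run manifest.  All floats at
    fixed 6-decimal precision for bit-stable diffs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    p = outdir / "effects.tsv"
    effects_frame.to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
    paths["effects"] = p
    for muscle, frame in asr_frames.items():
        p = outdir / f"asr_{muscle}.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
        paths[f"asr_{muscle}"] = p
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    paths["manifest"] = p
    return paths


def asr_frame(tree: PhyloTree, asr) -> pd.DataFrame:
    """Tabulate an ASRResult: node id, parent id, one probability column per
    state, and the MAP state."""
    states = asr.model.states
    rows = []
    for node in tree.preorder():
        if node.is_leaf:
            continue
        probs = asr.node_probs[node.id]
        rows.append({"node_id": node.id,
                     "parent_id": node.parent.id if node.parent else -1,
                     **{f"p_{s}": float(p) for s, p in zip(states, probs)},
                     "map_state": asr.map_states[node.id],
                     "tied": node.id in asr.tied_nodes})
    return pd.DataFrame(rows)
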