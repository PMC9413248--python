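"""Readers and writers for the pipeline's on-disk formats.

Formats handled here: long peptide quantification tables (TSV/CSV, one row
per peptide x run), protein FASTA with reversed-decoy generation, GMT gene
sets, Newick dendrograms and the YAML run configuration. Missing intensity
values are encoded as absent rows, never as zeros or NA tokens, so that
aggregation downstream is unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import StudyDesign

log = logging.getLogger(__name__)

#: mandatory peptide-table columns; the mass pair is optional but joint
PEPTIDE_COLUMNS = ["peptide", "protein", "unique", "run", "intensity"]
MASS_COLUMNS = ["mz_theoretical", "mz_observed"]

DECOY_PREFIX = "REV_"


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------

def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_peptide_table(
    path: str | Path, design: StudyDesign, delimiter: str | None = None
) -> pd.DataFrame:
    """Read and validate a long-format peptide quantification table.

    Expected header: peptide, protein, unique (0/1), run, intensity, and
    optionally the pair mz_theoretical / mz_observed (Da). Rows are
    validated against the design's run ids and the table invariants:
    strictly positive intensities, positive masses, and uniqueness of the
    (peptide, protein, run) triplet.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table {path} missing mandatory column(s): {missing}")
    has_mass = all(c in df.columns for c in MASS_COLUMNS)
    if not has_mass and any(c in df.columns for c in MASS_COLUMNS):
        raise ValueError(f"mass columns must appear as a pair: {MASS_COLUMNS}")

    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    bad = df.index[~(intensity > 0) | intensity.isna()]
    if len(bad):
        rows = [int(i) + 2 for i in bad[:20]]  # 1-based, +1 for header
        raise ValueError(
            f"non-positive or non-numeric intensity in {path} at file row(s) {rows}"
        )
    df["intensity"] = intensity.astype(float)

    unknown = sorted(set(df["run"].astype(str)) - set(design.run_ids))
    if unknown:
        raise ValueError(f"run id(s) not in design: {unknown}")

    dup = df.duplicated(subset=["peptide", "protein", "run"], keep=False)
    if dup.any():
        first = df.loc[dup, ["peptide", "protein", "run"]].iloc[0]
        raise ValueError(
            "duplicate (peptide, protein, run) triplet: "
            f"({first['peptide']}, {first['protein']}, {first['run']})"
        )

    df["unique"] = df["unique"].astype(int).astype(bool)
    df["peptide"] = df["peptide"].astype(str)
    df["protein"] = df["protein"].astype(str)
    df["run"] = df["run"].astype(str)
    if has_mass:
        for c in MASS_COLUMNS:
            df[c] = pd.to_numeric(df[c])
            if (df[c] <= 0).any():
                raise ValueError(f"non-positive values in column {c}")
    cols = PEPTIDE_COLUMNS + (MASS_COLUMNS if has_mass else [])
    log.info("read %d peptide rows from %s", len(df), path)
    return df[cols].reset_index(drop=True)


def write_peptide_table(
    table: pd.DataFrame, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a peptide table in the dialect implied by the file extension."""
    path = Path(path)
    table.to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


# ---------------------------------------------------------------------------
# FASTA decoys
# ---------------------------------------------------------------------------

def make_reversed_decoys(fasta_path: str | Path, out_path: str | Path) -> int:
    """Append a sequence-reversed decoy for every FASTA record.

    Each target record ``>X`` gains a companion ``>REV_X`` whose sequence is
    the character reversal of the target's; targets are preserved, so the
    output holds exactly twice the input record count (returned).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA: {fasta_path}")
    ids = {r.id for r in records}
    out: list[SeqRecord] = []
    for rec in records:
        decoy_id = DECOY_PREFIX + rec.id
        if decoy_id in ids:
            raise ValueError(f"decoy id collision: {decoy_id} already present")
        out.append(rec)
        out.append(
            SeqRecord(Seq(str(rec.seq)[::-1]), id=decoy_id, description="reversed decoy")
        )
    SeqIO.write(out, str(out_path), "fasta")
    return len(out)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene/protein sets as parsed from a GMT file."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated id, description,
    members. Members are deduplicated (first occurrence order); lines with
    fewer than three fields are skipped and logged."""
    coll = GeneSetCollection()
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                log.warning("GMT %s line %d has <3 fields; skipped", path, lineno)
                n_skipped += 1
                continue
            set_id, desc, *members = fields
            if set_id in coll.sets:
                raise ValueError(f"duplicate set id {set_id!r} in {path}")
            coll.sets[set_id] = list(dict.fromkeys(m for m in members if m))
            coll.descriptions[set_id] = desc
    if not coll.sets:
        log.warning("GMT %s produced an empty collection (%d skipped)", path, n_skipped)
    return coll


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;'\"[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(dendrogram) -> str:
    """Serialize an ultrametric dendrogram to a Newick string.

    Accepts any object with a scipy-format ``linkage`` matrix and a
    ``labels`` sequence (see :class:`top3quant.profile.Dendrogram`). Branch
    lengths are merge-height differences, so leaf-to-root path length equals
    the root merge height for every leaf.
    """
    Z = np.asarray(dendrogram.linkage, dtype=float)
    labels = list(dendrogram.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("dendrogram must have at least 2 leaves")
    if Z.shape[0] != n - 1:
        raise ValueError("linkage matrix inconsistent with label count")

    def render(node: int, parent_height: float) -> str:
        if node < n:
            return f"{_quote_label(labels[node])}:{parent_height:g}"
        row = Z[node - n]
        h = float(row[2])
        left = render(int(row[0]), h)
        right = render(int(row[1]), h)
        return f"({left},{right}):{parent_height - h:g}"

    row = Z[-1]
    h = float(row[2])
    left = render(int(row[0]), h)
    right = render(int(row[1]), h)
    return f"({left},{right});"


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load the YAML run configuration (design, thresholds, paths)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def design_from_config(cfg: dict) -> StudyDesign:
    if "design" not in cfg:
        raise ValueError("config has no 'design' section")
    return StudyDesign.from_records(cfg["design"])
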