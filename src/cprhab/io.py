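"""Readers and writers for the plain-text formats used across the pipeline.

All tabular artifacts are tab-separated with an optional leading comment
header (``# cprhab ...``) recording provenance; readers skip ``#`` lines.
Trees are Newick (via dendropy), marker proteins are FASTA (via Biopython).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, header_note: str | None = None,
              index: bool = False) -> Path:
    """Write a TSV, optionally prefixed with a ``# cprhab`` provenance line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# cprhab {header_note}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_ani_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square ANI matrix (genome ids as header row and first column)."""
    mat = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    mat.columns = mat.columns.astype(str)
    mat.index = mat.index.astype(str)
    return mat


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    return path


def write_json(obj: Mapping, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
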