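"""File formats: FASTA sequences, label companions, model JSON, manifests.

Sequences travel as plain FASTA (dice symbols '1'-'6' are legal FASTA
payload characters); true state paths travel in a FASTA-like companion
file whose records carry one state-code character per position, with ids
matching the sequence file.  A model and its parameterization serialise
to a single versioned JSON document so file and code cannot drift.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    Coord,
    FactorGroup,
    HmmModel,
    LabeledDataset,
    LabeledSequence,
    Member,
    Parameterization,
)

__all__ = [
    "read_sequences",
    "read_labels",
    "attach_labels",
    "write_dataset",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "write_manifest",
]

MODEL_FORMAT = "hmmtrain-model"
MODEL_VERSION = 1


# --------------------------------------------------------------------------
# FASTA sequences and labels
# --------------------------------------------------------------------------

def read_sequences(path, model: HmmModel | None = None) -> list[LabeledSequence]:
    """Read FASTA records, order-preserving, ids retained.

    With a model, symbols are validated against its alphabet (with
    uppercase normalisation when the alphabet is alphabetic, e.g. DNA);
    an out-of-alphabet symbol raises naming the record, position and
    symbol.  An empty file raises.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out = []
    normalize = model is not None and all(c.isalpha() for c in model.alphabet)
    for rec in records:
        symbols = str(rec.seq)
        if normalize:
            symbols = symbols.upper()
        if model is not None:
            try:
                model.encode(symbols)
            except ValueError as exc:
                raise ValueError(f"{path}: record {rec.id!r}: {exc}") from None
        out.append(LabeledSequence(symbols=symbols, id=rec.id))
    return out


def read_labels(path, model: HmmModel) -> dict[str, str]:
    """Read a FASTA-like label companion; returns id -> code string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no label records found")
    out = {}
    for rec in records:
        codes = str(rec.seq)
        try:
            model.encode_labels(codes)
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec.id!r}: {exc}") from None
        out[rec.id] = codes
    return out


def attach_labels(sequences: list[LabeledSequence], labels: dict[str, str],
                  model: HmmModel) -> list[LabeledSequence]:
    """Attach label strings to sequences by record id."""
    out = []
    for seq in sequences:
        if seq.id not in labels:
            raise KeyError(f"no labels for record {seq.id!r}")
        codes = labels[seq.id]
        if len(codes) != len(seq.symbols):
            raise ValueError(
                f"record {seq.id!r}: label length {len(codes)} != "
                f"sequence length {len(seq.symbols)}")
        out.append(LabeledSequence(symbols=seq.symbols,
                                   labels=model.encode_labels(codes),
                                   id=seq.id))
    return out


def write_dataset(dataset: LabeledDataset, prefix, model: HmmModel) -> dict:
    """Write FASTA + label companion + metadata JSON; returns file paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = prefix.with_suffix(".fasta")
    labf = prefix.parent / (prefix.name + ".labels.fasta")
    meta = prefix.parent / (prefix.name + ".meta.json")
    seq_records, lab_records = [], []
    for seq in dataset:
        seq_records.append(SeqRecord(Seq(seq.symbols), id=seq.id, description=""))
        if seq.labels is not None:
            lab_records.append(SeqRecord(Seq(model.decode_labels(seq.labels)),
                                         id=seq.id, description=""))
    SeqIO.write(seq_records, str(fasta), "fasta")
    paths = {"sequences": str(fasta)}
    if lab_records:
        SeqIO.write(lab_records, str(labf), "fasta")
        paths["labels"] = str(labf)
    meta.write_text(json.dumps(dataset.metadata, indent=2, sort_keys=True) + "\n")
    paths["metadata"] = str(meta)
    return paths


def read_dataset(fasta_path, labels_path, model: HmmModel) -> LabeledDataset:
    seqs = read_sequences(fasta_path, model)
    if labels_path is not None:
        seqs = attach_labels(seqs, read_labels(labels_path, model), model)
    return LabeledDataset(sequences=seqs)


# --------------------------------------------------------------------------
# model JSON
# --------------------------------------------------------------------------

def model_to_dict(model: HmmModel, par: Parameterization) -> dict:
    def coords_out(coords):
        return [{"coord": list(c), "const": coord.const,
                 "factors": [list(f) for f in coord.factors]}
                for c, coord in sorted(coords.items())]

    return {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "states": model.states,
        "state_codes": model.state_codes,
        "alphabet": model.alphabet,
        "trans": model.trans.tolist(),
        "emit": model.emit.tolist(),
        "groups": [{"name": g.name, "kind": g.kind,
                    "members": [{"name": m.name, "role": m.role}
                                for m in g.members]}
                   for g in par.groups.values()],
        "trans_coords": coords_out(par.trans_coords),
        "emit_coords": coords_out(par.emit_coords),
        "default_values": par.default_values,
        "relabelings": par.relabelings,
    }


def model_from_dict(doc: dict) -> tuple[HmmModel, Parameterization]:
    if doc.get("format") != MODEL_FORMAT:
        raise ValueError("not an hmmtrain model document")
    if doc.get("version") != MODEL_VERSION:
        raise ValueError(f"unsupported model document version {doc.get('version')}")
    model = HmmModel(states=list(doc["states"]), alphabet=list(doc["alphabet"]),
                     trans=np.array(doc["trans"]), emit=np.array(doc["emit"]),
                     state_codes=list(doc["state_codes"]))

    def coords_in(entries):
        return {tuple(e["coord"]): Coord(float(e["const"]),
                                         [tuple(f) for f in e["factors"]])
                for e in entries}

    groups = {g["name"]: FactorGroup(g["name"],
                                     [Member(m["name"], m["role"])
                                      for m in g["members"]],
                                     kind=g["kind"])
              for g in doc["groups"]}
    par = Parameterization(groups=groups,
                           trans_coords=coords_in(doc["trans_coords"]),
                           emit_coords=coords_in(doc["emit_coords"]),
                           default_values=dict(doc["default_values"]),
                           relabelings=[dict(r) for r in doc["relabelings"]])
    problems = par.validate()
    if problems:
        raise ValueError(f"invalid model document: {problems}")
    return model, par


def save_model(path, model: HmmModel, par: Parameterization) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model, par), indent=2) + "\n")


def load_model(path) -> tuple[HmmModel, Parameterization]:
    return model_from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------

def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, command: list[str], config: dict,
                   seed: int | None, inputs: list[str]) -> None:
    """Record everything needed to reproduce a run byte-for-byte."""
    from . import __version__

    doc = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "inputs": {str(p): _digest(p) for p in inputs if Path(p).is_file()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
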