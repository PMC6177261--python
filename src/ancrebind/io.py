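"""File-format dialects: FASTA alignments (Biopython), Newick trees with
internal-node labels (dendropy), tab-separated tables with '#' comments and a
required header row, and JSON reports. Parse errors name the file, line, and
field involved."""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .asr import AncestralPosterior, AncestralSequenceSet
from .binding import Sensorgram, TitrationSeries
from .containers import AminoAlignment, PhyloTree
from .model import AMINO_ACIDS


def read_fasta_alignment(path) -> AminoAlignment:
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in names:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        names.append(rec.id)
        rows.append(str(rec.seq))
    if not names:
        raise ValueError(f"{path}: no FASTA records found")
    try:
        return AminoAlignment(names=names, rows=rows)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def write_fasta(path, names_seqs: dict[str, str] | AminoAlignment) -> None:
    if isinstance(names_seqs, AminoAlignment):
        items = zip(names_seqs.names, names_seqs.rows)
    else:
        items = names_seqs.items()
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def read_newick(path) -> PhyloTree:
    text = Path(path).read_text()
    try:
        return PhyloTree.from_newick(text)
    except Exception as e:
        raise ValueError(f"{path}: failed to parse Newick: {e}") from None


def write_newick(path, tree: PhyloTree) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_tsv(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Tab-separated with '#' comment lines and a mandatory header row."""
    lines = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.lstrip().startswith("#") or not raw.strip():
                continue
            lines.append((lineno, raw.rstrip("\n")))
    if not lines:
        raise ValueError(f"{path}: no data rows")
    header = lines[0][1].split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: line {lines[0][0]}: header missing "
                         f"required columns {missing} (found {header})")
    ncol = len(header)
    for lineno, line in lines[1:]:
        nf = len(line.split("\t"))
        if nf != ncol:
            raise ValueError(f"{path}: line {lineno}: expected {ncol} "
                             f"fields, found {nf}")
    buf = _io.StringIO("\n".join(l for _, l in lines))
    return pd.read_csv(buf, sep="\t")


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


# --- typed readers ---------------------------------------------------------


def read_titration_tsv(path, D: float, motif: str = "") -> TitrationSeries:
    df = read_tsv(path, required=("protein_M", "fraction_bound"))
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    if rep is not None and np.unique(rep).size == 1:
        rep = None
    return TitrationSeries(D=D, P=df["protein_M"].to_numpy(float),
                           F=df["fraction_bound"].to_numpy(float),
                           motif=motif, replicate=rep)


def write_titration_tsv(path, series: TitrationSeries) -> None:
    df = pd.DataFrame({"protein_M": series.P, "fraction_bound": series.F})
    df["replicate"] = (series.replicate if series.replicate is not None else 1)
    write_tsv(path, df)


def read_sensorgram_tsv(path) -> list[Sensorgram]:
    df = read_tsv(path, required=("time_s", "response_RU", "conc_M", "phase"))
    out = []
    for (c0, phase), grp in df.groupby(["conc_M", "phase"], sort=True):
        grp = grp.sort_values("time_s")
        out.append(Sensorgram(t=grp["time_s"].to_numpy(float),
                              R=grp["response_RU"].to_numpy(float),
                              c0=float(c0), phase=str(phase)))
    return out


def write_sensorgram_tsv(path, grams: list[Sensorgram]) -> None:
    frames = [pd.DataFrame({"time_s": g.t, "response_RU": g.R,
                            "conc_M": g.c0, "phase": g.phase}) for g in grams]
    write_tsv(path, pd.concat(frames, ignore_index=True))


def write_posterior_tsv(path, posterior: AncestralPosterior,
                        seqs: AncestralSequenceSet | None = None) -> None:
    df = pd.DataFrame(posterior.probs, columns=list(AMINO_ACIDS))
    df.insert(0, "site", np.arange(1, posterior.n_sites + 1))
    df.insert(0, "node", posterior.node_label)
    df["ml_state"] = [AMINO_ACIDS[i] for i in posterior.ml_states]
    if seqs is not None:
        df["altall_state"] = list(seqs.altall_sequence)
    write_tsv(path, df)


def write_json(path, obj) -> None:
    def default(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if hasattr(v, "to_dict"):
            return v.to_dict()
        raise TypeError(f"not JSON-serializable: {type(v)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
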