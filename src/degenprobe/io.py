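"""Readers and writers for the pipeline's plain-text formats."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

from .design import ProbeCandidate, ProteinAlignment
from .screen import CrossHybHit


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_alignment(
    path: str | Path, reference_id: str | None = None, fmt: str | None = None
) -> ProteinAlignment:
    """Read an aligned FASTA or Clustal file.

    Format is sniffed from the first line when not given; the reference
    defaults to the first record.
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"cannot read alignment {path}: {exc}") from exc
    records = tuple((r.id, str(r.seq).upper()) for r in aln)
    return ProteinAlignment(
        records=records, reference_id=reference_id or records[0][0]
    )


def write_probe_table(path: str | Path, probes: Sequence[ProbeCandidate]) -> None:
    pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in probes],
            "sequence": [p.seq for p in probes],
            "start": [p.start_nt for p in probes],
            "end": [p.end_nt for p in probes],
            "degeneracy": [p.degeneracy for p in probes],
            "inosine_count": [p.inosine_count for p in probes],
            "total_degeneracy": [p.total_degeneracy for p in probes],
            "crosshyb_count": [
                "" if p.crosshyb_count is None else p.crosshyb_count for p in probes
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> list[ProbeCandidate]:
    df = pd.read_csv(path, sep="\t", dtype={"crosshyb_count": "object"})
    out = []
    for _, row in df.iterrows():
        ch = row.get("crosshyb_count")
        out.append(
            ProbeCandidate(
                probe_id=str(row["probe_id"]),
                seq=str(row["sequence"]),
                start_nt=int(row["start"]),
                end_nt=int(row["end"]),
                degeneracy=int(row["degeneracy"]),
                inosine_count=int(row["inosine_count"]),
                total_degeneracy=int(row["total_degeneracy"]),
                crosshyb_count=None if pd.isna(ch) or ch == "" else int(ch),
            )
        )
    return out


def write_hit_report(path: str | Path, hits: Sequence[CrossHybHit]) -> None:
    pd.DataFrame(
        {
            "probe_id": [h.probe_id for h in hits],
            "variant": [h.variant_seq for h in hits],
            "target_id": [h.target_id for h in hits],
            "strand": [h.strand for h in hits],
            "position": [h.target_start for h in hits],
            "identity": [round(h.identity_pct, 2) for h in hits],
            "stretch": [h.longest_stretch for h in hits],
            "classification": [h.classification for h in hits],
            "cluster_id": [h.cluster_id for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` configuration (lines starting with # ignored)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def write_config(path: str | Path, cfg: dict[str, object]) -> None:
    Path(path).write_text("".join(f"{k} = {v}\n" for k, v in cfg.items()))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Feature TSV (probe_id, x, y, intensity, probe_class, replicate).

    Also accepts the documented .pair-style column layout (PROBE_ID, X, Y,
    PM) by renaming; probe class then defaults by RANDOM prefix in the id.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "pm" in cols and "intensity" not in cols:
        df = df.rename(columns={cols["pm"]: "intensity"})
    df = df.rename(columns={c: c.lower() for c in df.columns})
    if "probe_class" not in df.columns and "probe_id" in df.columns:
        df["probe_class"] = [
            "random" if str(p).upper().startswith("RANDOM") else "target"
            for p in df["probe_id"]
        ]
    if "replicate" not in df.columns:
        df["replicate"] = df.groupby("probe_id").cumcount() + 1
    return df
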