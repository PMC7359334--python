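"""Readers/writers and the run manifest.

All genomic coordinates are 0-based half-open (BED convention), in memory
and on disk. TSV outputs carry ``#``-prefixed metadata lines before the
header and deterministic column and row order, so identical runs give
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__

BED6_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


def read_bed(path) -> pd.DataFrame:
    """Parse BED3/BED6; malformed lines raise with their line number."""
    rows = []
    n_fields = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 tab-separated "
                                 f"fields, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(f"{path}:{ln}: invalid interval "
                                 f"[{start}, {end})")
            if n_fields is None:
                n_fields = min(len(parts), 6)
            rows.append((parts[0], start, end, *parts[3:6]))
    if not rows:
        return pd.DataFrame(columns=list(BED6_COLUMNS[:n_fields or 3]))
    width = max(len(r) for r in rows)
    cols = list(BED6_COLUMNS[:width])
    return pd.DataFrame(rows, columns=cols)


def write_bed(df: pd.DataFrame, path) -> None:
    """Write BED (sorted by chrom, start); extra columns beyond BED6 are
    dropped, known BED columns emitted in canonical order."""
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    out = df[cols].sort_values(["chrom", "start", "end"],
                               kind="stable") if len(df) else df[cols]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedpe(df: pd.DataFrame, path) -> None:
    """Fragments as collapsed BEDPE (chrom/start/end of the outer span)."""
    write_bed(df[["chrom", "start", "end"]], path)


def write_tsv(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bedgraph(track: pd.DataFrame, value_col: str, path) -> None:
    """Per-bin values as bedGraph; NA bins are skipped."""
    sub = track.dropna(subset=[value_col])
    sub[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record tying every pipeline output to its config and
    seed."""

    config: dict
    seed: int
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)

    def register(self, name: str, path) -> None:
        self.outputs[name] = str(path)
        self.digests[name] = file_digest(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "seed": self.seed,
                       "config": self.config, "outputs": self.outputs,
                       "digests": self.digests}, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(config=d["config"], seed=d["seed"], version=d["version"],
                   outputs=d["outputs"], digests=d["digests"])
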