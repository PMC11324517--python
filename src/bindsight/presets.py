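"""Loaders for the packaged ring/moiety, helix-range and residue-mapping tables."""

from __future__ import annotations

import csv
import tomllib
from importlib import resources

from .interactions import RingSpec

__all__ = [
    "load_ring_config",
    "default_ring_specs",
    "load_helix_ranges",
    "load_residue_mapping",
]


def _data_text(name: str) -> str:
    return resources.files("bindsight.data").joinpath(name).read_text()


def load_ring_config(path: str | None = None) -> dict:
    """Ring and moiety atom-name groups (packaged defaults or a user TOML)."""
    if path is None:
        text = _data_text("rings.toml")
    else:
        with open(path) as fh:
            text = fh.read()
    return tomllib.loads(text)


def default_ring_specs(
    trp_chain: str | None = "A",
    trp_resseq: int | None = None,
    ligand_chain: str | None = None,
    ligand_resseq: int = 901,
) -> tuple[RingSpec, RingSpec]:
    """The packaged indole / adenine ring pair as resolvable RingSpecs."""
    cfg = load_ring_config()
    indole = cfg["rings"]["w84_indole"]
    adenine = cfg["rings"]["mrs_adenine"]
    return (
        RingSpec(
            chain=trp_chain,
            resseq=trp_resseq if trp_resseq is not None else indole["resseq"],
            atom_names=tuple(indole["atoms"]),
        ),
        RingSpec(
            chain=ligand_chain,
            resseq=ligand_resseq,
            atom_names=tuple(adenine["atoms"]),
        ),
    )


def _read_csv(text: str) -> list[dict]:
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    return list(csv.DictReader(lines))


def load_helix_ranges(path: str | None = None) -> dict[str, tuple[str, int, int]]:
    """helix name -> (chain, start, end) in full-length numbering."""
    text = _data_text("helix_ranges.csv") if path is None else open(path).read()
    out = {}
    for row in _read_csv(text):
        out[row["helix"]] = (row["chain"], int(row["start"]), int(row["end"]))
    return out


def load_residue_mapping(
    pair: str, helices: list[str] | None = None, path: str | None = None
) -> list[tuple[str, int, str, int]]:
    """Per-residue (ref_chain, ref_resseq, target_chain, target_resseq) rows.

    The packaged table stores per-helix constant offsets; rows are
    expanded here to one entry per residue of the helix range.
    """
    text = _data_text("residue_mapping.csv") if path is None else open(path).read()
    mapping = []
    for row in _read_csv(text):
        if row["pair"] != pair:
            continue
        if helices is not None and row["helix"] not in helices:
            continue
        off = int(row["offset"])
        for r in range(int(row["ref_start"]), int(row["ref_end"]) + 1):
            mapping.append((row["ref_chain"], r, row["target_chain"], r + off))
    if not mapping:
        raise ValueError(f"no mapping rows for pair {pair!r}")
    return mapping
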