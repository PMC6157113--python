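"""Construct regions of interest (ROIs) around anchor CpGs or from lists.

An ROI is either (a) all markers of a chosen universe lying within a
symmetric window of ``+/- w`` kilobase pairs around an anchor marker, with
both boundaries inclusive, or (b) an explicit marker list (e.g. the CpGs
of one intron).  Window arithmetic uses 1-based inclusive positions; a
0-kbp window therefore contains the anchor plus any marker at exactly the
anchor's position, which makes the single-marker kernel test comparable to
ordinary single-marker regression.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .core_data import MarkerAnnotation, Region, RegionSet
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)


def build_window_region(name: str, anchor: str, window_kbp: float,
                        annotation: MarkerAnnotation,
                        universe: Sequence[str]) -> Region:
    """All universe markers within ``window_kbp`` of the anchor, inclusive.

    Members are restricted to the anchor's chromosome and sorted by
    position (ties by marker id).  The anchor is always a member, whether
    or not it appears in the universe.
    """
    if window_kbp < 0:
        raise ConfigurationError("window_kbp must be non-negative")
    chrom, pos, _ = annotation.lookup(anchor)
    half_bp = window_kbp * 1000.0
    candidates = annotation.on_chromosome(chrom)
    in_universe = candidates["marker_id"].isin(set(universe) | {anchor})
    within = (candidates["pos"] - pos).abs() <= half_bp
    hits = candidates[in_universe & within]
    hits = hits.sort_values(["pos", "marker_id"])
    members = tuple(hits["marker_id"])
    if anchor not in members:  # anchor missing from universe slice
        members = tuple(sorted({*members, anchor},
                               key=lambda m: (annotation.lookup(m)[1], m)))
    return Region(name=name, members=members, anchor=anchor,
                  window_kbp=float(window_kbp))


def build_explicit_region(name: str, member_ids: Sequence[str],
                          annotation: MarkerAnnotation) -> Region:
    """Region from an explicit list; order kept, duplicates removed."""
    if not member_ids:
        raise ConfigurationError(f"region {name!r}: empty member list")
    seen: dict[str, None] = {}
    for mid in member_ids:
        if mid not in annotation:
            raise ConfigurationError(
                f"region {name!r}: member {mid!r} is not annotated"
            )
        if mid in seen:
            logger.warning("region %r: duplicated member %r removed",
                           name, mid)
        seen[mid] = None
    return Region(name=name, members=tuple(seen), anchor=None,
                  window_kbp=None)


def nearest_marker(query_id: str, annotation: MarkerAnnotation,
                   candidate_ids: Sequence[str]) -> str:
    """Nearest same-chromosome candidate by |position difference|.

    Ties break toward the lower position, then the lexicographically
    smaller id, so the pairing is deterministic.
    """
    chrom, pos, _ = annotation.lookup(query_id)
    best: tuple[float, int, str] | None = None
    for cid in candidate_ids:
        if cid == query_id:
            continue
        c_chrom, c_pos, _ = annotation.lookup(cid)
        if c_chrom != chrom:
            continue
        key = (abs(c_pos - pos), c_pos, cid)
        if best is None or key < best:
            best = key
    if best is None:
        raise ConfigurationError(
            f"no candidate marker on chromosome {chrom!r} for {query_id!r}"
        )
    return best[2]


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

def read_region_config(path: str | Path, annotation: MarkerAnnotation,
                       universe: Sequence[str]) -> RegionSet:
    """Build a RegionSet from a YAML or TSV ROI configuration.

    YAML: a list of mappings, each either
    ``{name, anchor, window_kbp}`` or ``{name, members: [ids...]}``.
    TSV: rows ``name<TAB>anchor<TAB>window_kbp`` or
    ``name<TAB>comma,joined,member,ids``.
    """
    path = Path(path)
    entries: list[dict]
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, list):
            raise ConfigurationError("region YAML must be a list of entries")
        entries = raw
    else:
        entries = []
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype=str).fillna("")
        for _, row in df.iterrows():
            fields = [f for f in row.tolist() if f != ""]
            if len(fields) == 3:
                entries.append({"name": fields[0], "anchor": fields[1],
                                "window_kbp": float(fields[2])})
            elif len(fields) == 2:
                entries.append({"name": fields[0],
                                "members": fields[1].split(",")})
            else:
                raise ConfigurationError(
                    f"region TSV row has {len(fields)} fields, expected 2 or 3"
                )
    regions = []
    for entry in entries:
        if "members" in entry:
            regions.append(build_explicit_region(
                entry["name"], list(entry["members"]), annotation))
        else:
            regions.append(build_window_region(
                entry["name"], entry["anchor"], float(entry["window_kbp"]),
                annotation, universe))
    return RegionSet(regions=tuple(regions))
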