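"""Strain-level translocation calls from marker-gene pileups.

The test works on species-specific marker genes: per sample, reads piled up
against each marker give coverage breadth (fraction of positions with depth
>= 1) and a set of consensus-style SNPs.  A marker is eligible only when its
breadth strictly exceeds ``breadth_min`` (default 0.4) in BOTH samples of a
subject's uterus/vagina pair; an "identical SNP" is an exact
(marker, position, allele) match across the pair on eligible markers.

A species is called the same strain in both sites when all identical SNPs of
one site are contained in the other (containment >= ``containment_min``,
default 1.0, i.e. full containment).  Direction: if the uterine SNP set is
fully contained in the vaginal one AND the vagina carries extra SNPs, the
strain moved vagina -> uterus (and symmetrically); equal nonempty sets leave
the direction undetermined.  Coordinates are 1-based per mpileup convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StrainError",
    "MarkerInfo",
    "MarkerIndex",
    "PositionRecord",
    "MarkerSNPProfile",
    "StrainSharingCall",
    "read_marker_index",
    "write_marker_index",
    "parse_pileup",
    "call_snps",
    "marker_breadth",
    "identical_snps",
    "strain_sharing",
    "cohort_strain_summary",
]

ALLELES = ("A", "C", "G", "T")
BREADTH_MIN = 0.4
CONTAINMENT_MIN = 1.0
MIN_DEPTH = 4
MIN_ALT_FRAC = 0.8


class StrainError(ValueError):
    """Raised on malformed pileups, indexes, or profiles."""


@dataclass
class MarkerInfo:
    species: str
    length: int
    reference: str | None = None  # optional reference sequence

    def __post_init__(self) -> None:
        if self.length < 1:
            raise StrainError("marker length must be >= 1")
        if self.reference is not None and len(self.reference) != self.length:
            raise StrainError("reference sequence length mismatch")


@dataclass
class MarkerIndex:
    """marker_id -> (species, length, optional reference sequence)."""

    markers: dict[str, MarkerInfo]

    def __post_init__(self) -> None:
        if not self.markers:
            raise StrainError("marker index is empty")

    def species_of(self, marker_id: str) -> str:
        return self[marker_id].species

    def __getitem__(self, marker_id: str) -> MarkerInfo:
        try:
            return self.markers[marker_id]
        except KeyError:
            raise StrainError(f"marker {marker_id!r} absent from index") from None

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.markers

    def markers_of_species(self, species: str) -> list[str]:
        return [m for m, info in self.markers.items() if info.species == species]

    @property
    def species(self) -> list[str]:
        return sorted({info.species for info in self.markers.values()})


def read_marker_index(path: str | Path) -> MarkerIndex:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("marker_id", "species", "length"):
        if col not in df.columns:
            raise StrainError(f"{path}: missing column {col!r}")
    markers: dict[str, MarkerInfo] = {}
    for _, row in df.iterrows():
        mid = row["marker_id"]
        if mid in markers:
            raise StrainError(f"{path}: duplicate marker id {mid!r}")
        markers[mid] = MarkerInfo(row["species"], int(row["length"]))
    return MarkerIndex(markers)


def write_marker_index(index: MarkerIndex, path: str | Path) -> None:
    rows = [
        {"marker_id": mid, "species": info.species, "length": info.length}
        for mid, info in index.markers.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class PositionRecord:
    marker: str
    position: int  # 1-based
    ref_base: str
    depth: int
    ref_count: int
    alt_counts: dict[str, int]


@dataclass
class MarkerSNPProfile:
    """Per-sample marker coverage and consensus SNP set."""

    sample_id: str
    covered: dict[str, set[int]]  # marker -> 1-based covered positions
    snps: set[tuple[str, int, str]]  # (marker, position, alt allele)
    depths: dict[tuple[str, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for marker, pos, alt in self.snps:
            if alt not in ALLELES:
                raise StrainError(f"alt allele {alt!r} not in {ALLELES}")
            if pos not in self.covered.get(marker, set()):
                raise StrainError(
                    f"SNP at uncovered position {marker}:{pos} in "
                    f"{self.sample_id!r}"
                )

    def species_snps(self, species: str, index: MarkerIndex,
                     markers: set[str] | None = None) -> set[tuple[str, int, str]]:
        wanted = set(index.markers_of_species(species))
        if markers is not None:
            wanted &= markers
        return {s for s in self.snps if s[0] in wanted}


# ---------------------------------------------------------------------------
# pileup parsing


def _parse_base_column(bases: str, line_no: int) -> tuple[int, dict[str, int]]:
    """Count reference matches and alternate alleles in an mpileup base string.

    Handles '.'/',' (reference), explicit base letters (alternates),
    '^'+mapq start tokens, '$' end tokens, '+n'/'-n' indel runs (skipped) and
    '*' deletions (depth but no allele)."""
    ref = 0
    alts: dict[str, int] = {}
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c in ".,":
            ref += 1
            i += 1
        elif c == "^":
            if i + 1 >= n:
                raise StrainError(f"line {line_no}: dangling '^' start token")
            i += 2  # consume the mapping-quality character
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise StrainError(f"line {line_no}: malformed indel run")
            run = int(bases[i + 1:j])
            if j + run > n:
                raise StrainError(f"line {line_no}: truncated indel run")
            i = j + run
        elif c == "*":
            i += 1  # deletion placeholder: depth, no allele
        elif c.upper() in "ACGTN":
            if c.upper() != "N":
                alts[c.upper()] = alts.get(c.upper(), 0) + 1
            i += 1
        else:
            raise StrainError(f"line {line_no}: unexpected character {c!r}")
    return ref, alts


def parse_pileup(
    source: str | Path, index: MarkerIndex
) -> dict[tuple[str, int], PositionRecord]:
    """Parse 6-column samtools-mpileup text into per-position allele counts.

    ``source`` may be a path or literal pileup text (detected by newlines/
    tabs)."""
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif "\t" in source or "\n" in source:
        text = source
    else:
        text = Path(source).read_text(encoding="utf-8")
    records: dict[tuple[str, int], PositionRecord] = {}
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise StrainError(f"line {line_no}: expected 6 columns, got {len(fields)}")
        marker, pos_s, ref_base, depth_s, bases, _quals = fields[:6]
        if marker not in index:
            raise StrainError(f"line {line_no}: marker {marker!r} absent from index")
        pos = int(pos_s)
        if not 1 <= pos <= index[marker].length:
            raise StrainError(
                f"line {line_no}: position {pos} outside marker "
                f"{marker!r} (length {index[marker].length})"
            )
        depth = int(depth_s)
        ref_count, alt_counts = _parse_base_column(bases, line_no)
        records[(marker, pos)] = PositionRecord(
            marker, pos, ref_base.upper(), depth, ref_count, alt_counts
        )
    return records


def call_snps(
    records: dict[tuple[str, int], PositionRecord],
    min_depth: int = MIN_DEPTH,
    min_alt_frac: float = MIN_ALT_FRAC,
    sample_id: str = "sample",
) -> MarkerSNPProfile:
    """Consensus-style SNP calls: a SNP at (marker, pos, alt) requires depth
    >= ``min_depth`` and majority-alternate frequency >= ``min_alt_frac``.
    Covered positions are those with depth >= 1."""
    if min_alt_frac <= 0.5:
        raise StrainError("min_alt_frac must exceed 0.5 (unique majority)")
    covered: dict[str, set[int]] = {}
    depths: dict[tuple[str, int], int] = {}
    snps: set[tuple[str, int, str]] = set()
    for (marker, pos), rec in records.items():
        if rec.depth >= 1:
            covered.setdefault(marker, set()).add(pos)
            depths[(marker, pos)] = rec.depth
        if rec.depth >= min_depth and rec.alt_counts:
            alt, count = max(rec.alt_counts.items(), key=lambda kv: (kv[1], kv[0]))
            if count / rec.depth >= min_alt_frac:
                snps.add((marker, pos, alt))
    return MarkerSNPProfile(sample_id, covered, snps, depths)


# ---------------------------------------------------------------------------
# breadth gating, identical SNPs, sharing calls


def marker_breadth(
    profile: MarkerSNPProfile, marker: str, index: MarkerIndex
) -> float:
    """Coverage breadth = covered positions / marker length."""
    return len(profile.covered.get(marker, ())) / index[marker].length


def _eligible_markers(
    pa: MarkerSNPProfile,
    pb: MarkerSNPProfile,
    index: MarkerIndex,
    species: str,
    breadth_min: float,
) -> set[str]:
    return {
        m
        for m in index.markers_of_species(species)
        if marker_breadth(pa, m, index) > breadth_min
        and marker_breadth(pb, m, index) > breadth_min
    }


def identical_snps(
    profile_a: MarkerSNPProfile,
    profile_b: MarkerSNPProfile,
    index: MarkerIndex,
    breadth_min: float = BREADTH_MIN,
) -> dict[str, set[tuple[str, int, str]]]:
    """Per-species exact (marker, position, allele) matches across a pair,
    restricted to markers whose breadth strictly exceeds ``breadth_min`` in
    both samples.  Species with zero mutually eligible markers are omitted
    (with a logged note)."""
    out: dict[str, set[tuple[str, int, str]]] = {}
    for species in index.species:
        eligible = _eligible_markers(profile_a, profile_b, index, species, breadth_min)
        if not eligible:
            logger.info(
                "species %s: no mutually eligible marker (breadth <= %.2f); omitted",
                species, breadth_min,
            )
            continue
        sa = profile_a.species_snps(species, index, eligible)
        sb = profile_b.species_snps(species, index, eligible)
        out[species] = sa & sb
    return out


@dataclass
class StrainSharingCall:
    subject_id: str
    species: str
    n_snps_uterus: int
    n_snps_vagina: int
    n_identical: int
    containment_u_in_v: float  # |S_U ∩ S_V| / |S_U|; NaN when S_U is empty
    containment_v_in_u: float
    same_strain: bool
    direction: str  # vagina_to_uterus | uterus_to_vagina | undetermined | none
    status: str = "called"  # or "undetermined_by_absence"


def strain_sharing(
    profile_u: MarkerSNPProfile,
    profile_v: MarkerSNPProfile,
    index: MarkerIndex,
    breadth_min: float = BREADTH_MIN,
    containment_min: float = CONTAINMENT_MIN,
    subject_id: str = "subject",
) -> list[StrainSharingCall]:
    """Same-strain and directionality calls for every species with at least
    one mutually eligible marker."""
    calls = []
    for species in index.species:
        eligible = _eligible_markers(profile_u, profile_v, index, species, breadth_min)
        if not eligible:
            continue
        s_u = profile_u.species_snps(species, index, eligible)
        s_v = profile_v.species_snps(species, index, eligible)
        ident = s_u & s_v
        if not s_u and not s_v:
            calls.append(
                StrainSharingCall(
                    subject_id, species, 0, 0, 0, float("nan"), float("nan"),
                    False, "undetermined", status="undetermined_by_absence",
                )
            )
            continue
        c_uv = len(ident) / len(s_u) if s_u else float("nan")
        c_vu = len(ident) / len(s_v) if s_v else float("nan")
        uv_ok = bool(s_u) and c_uv >= containment_min
        vu_ok = bool(s_v) and c_vu >= containment_min
        same = uv_ok or vu_ok
        if uv_ok and (s_v - s_u):
            direction = "vagina_to_uterus"
        elif vu_ok and (s_u - s_v):
            direction = "uterus_to_vagina"
        elif same:
            direction = "undetermined"  # equal nonempty sets
        else:
            direction = "none"
        calls.append(
            StrainSharingCall(
                subject_id, species, len(s_u), len(s_v), len(ident),
                c_uv, c_vu, same, direction,
            )
        )
    return calls


def cohort_strain_summary(calls: list[StrainSharingCall]) -> dict:
    """Cohort- and subject-level roll-up of sharing calls."""
    if not calls:
        raise StrainError("no strain-sharing calls to summarize")
    called = [c for c in calls if c.status == "called"]
    shared = [c for c in called if c.same_strain]
    v2u = [c for c in shared if c.direction == "vagina_to_uterus"]
    containments = [
        c.containment_u_in_v for c in called if np.isfinite(c.containment_u_in_v)
    ]
    per_subject: dict[str, dict[str, int]] = {}
    for c in calls:
        d = per_subject.setdefault(
            c.subject_id,
            {"species_tested": 0, "species_shared": 0, "vagina_to_uterus": 0},
        )
        if c.status == "called":
            d["species_tested"] += 1
            d["species_shared"] += int(c.same_strain)
            d["vagina_to_uterus"] += int(c.direction == "vagina_to_uterus")
    return {
        "n_calls": len(calls),
        "n_species_tested": len(called),
        "n_same_strain": len(shared),
        "fraction_shared": len(shared) / len(called) if called else float("nan"),
        "fraction_vagina_to_uterus": (
            len(v2u) / len(shared) if shared else float("nan")
        ),
        "containment_u_in_v_values": sorted(containments),
        "per_subject": per_subject,
    }
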