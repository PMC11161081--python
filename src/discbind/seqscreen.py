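"""Sequence-moiety screening and physicochemical triage scores.

The screen looks for 22-residue fragments of amphipathic helix length that
carry an acidic residue (D/E) at fragment position 4 and Gln/Arg at position
7 — the charge pair that anchors apoA1-like helices to the enzyme's lid
cavity via D4/E4-S236/K238 hydrogen bonds and, when arginine is present, an
R7-D73 salt bridge.  A generalized preset relaxes position 7 to an R at 7 or
a K/R at 10 or 11, the substitute contacts observed for apoE helix 1 and
apoB100 helix AS.

Candidate fragments are triaged with three scores: mean Hopp-Woods
hydrophilicity, mean Pace-Scholtz helical penalty (kcal/mol) and the
HELIQUEST-style hydrophobic moment on an ideal helical wheel (100 deg per
residue).  No hard cut-offs are applied: the report ranks, the user decides.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "STANDARD_AA",
    "MoietyPattern",
    "ResidueScale",
    "FragmentHit",
    "ScreenReport",
    "DE4_QR7",
    "DE4_R7_KR10_KR11",
    "load_scale",
    "load_packaged_sequence",
    "scan_fragments",
    "scan_pairs",
    "mean_hydrophilicity",
    "mean_helical_penalty",
    "hydrophobic_moment",
    "screen_proteome",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MoietyPattern:
    """Positional residue constraints on a fixed-length fragment window.

    ``constraints`` are conjunctive (every one must hold); ``any_of`` is an
    optional disjunctive group of which at least one must hold.  Positions
    are 1-based within the fragment.  Non-standard letters (X etc.) never
    satisfy a constraint.
    """

    window: int = 22
    constraints: tuple = ()
    any_of: tuple = ()
    name: str = "custom"

    def __post_init__(self) -> None:
        for pos, allowed in tuple(self.constraints) + tuple(self.any_of):
            if not (1 <= pos <= self.window):
                raise ValueError(f"position {pos} outside window 1..{self.window}")
            if not allowed:
                raise ValueError(f"empty residue set at position {pos}")
            bad = set(allowed) - STANDARD_AA
            if bad:
                raise ValueError(f"non-standard residues in pattern: {sorted(bad)}")

    def matches(self, fragment: str) -> bool:
        if len(fragment) != self.window:
            return False
        for pos, allowed in self.constraints:
            if fragment[pos - 1] not in allowed:
                return False
        if self.any_of:
            if not any(fragment[pos - 1] in allowed for pos, allowed in self.any_of):
                return False
        return True


#: D or E at fragment position 4 and Q or R at position 7, over a 22-mer window.
DE4_QR7 = MoietyPattern(
    window=22,
    constraints=((4, frozenset("DE")), (7, frozenset("QR"))),
    name="de4qr7",
)

#: Generalized predictor: D/E at 4, with R at 7 OR K/R at 10 OR K/R at 11.
DE4_R7_KR10_KR11 = MoietyPattern(
    window=22,
    constraints=((4, frozenset("DE")),),
    any_of=((7, frozenset("R")), (10, frozenset("KR")), (11, frozenset("KR"))),
    name="de4-r7kr10kr11",
)

PATTERN_PRESETS = {
    "de4qr7": DE4_QR7,
    "de4-r7kr10kr11": DE4_R7_KR10_KR11,
}


@dataclass(frozen=True)
class ResidueScale:
    """A per-residue value table (all 20 standard residues present)."""

    name: str
    values: dict
    unit: str = ""
    citation: str = ""

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")

    def of(self, sequence: str) -> np.ndarray:
        unknown = sorted(set(sequence) - set(self.values))
        if unknown:
            raise ValueError(
                f"residues {unknown} not in scale {self.name!r}; "
                "non-standard letters are not imputed"
            )
        return np.array([self.values[a] for a in sequence], dtype=float)


def load_scale(name: str) -> ResidueScale:
    """Load a packaged scale by name (hopp_woods, pace_scholtz, fauchere_pliska, eisenberg)."""
    ref = resources.files("discbind").joinpath(f"data/scales/{name}.json")
    try:
        doc = json.loads(ref.read_text(encoding="utf-8"))
    except FileNotFoundError:
        raise ValueError(f"no packaged scale named {name!r}") from None
    return ResidueScale(doc["name"], doc["values"], doc.get("unit", ""),
                        doc.get("citation", ""))


def load_packaged_sequence(name: str) -> str:
    """A packaged reference sequence: 'apoa1_mature' or 'peptide_22a'."""
    ref = resources.files("discbind").joinpath(f"data/sequences/{name}.fasta")
    with ref.open("r") as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    return str(rec.seq)


@dataclass
class FragmentHit:
    """One matching fragment with its triage scores."""

    protein_id: str
    start: int  # 1-based position in the supplied (mature) sequence
    sequence: str
    hydrophilicity_mean: Optional[float] = None
    helical_penalty_mean: Optional[float] = None
    hydrophobic_moment: Optional[float] = None

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


def scan_fragments(sequence: str, pattern: MoietyPattern = DE4_QR7,
                   protein_id: str = "") -> list:
    """All fragment starts (ascending) whose window satisfies the pattern.

    A sequence shorter than the window yields no hits (not an error).
    """
    sequence = str(sequence)
    hits = []
    for start in range(1, len(sequence) - pattern.window + 2):
        frag = sequence[start - 1 : start - 1 + pattern.window]
        if pattern.matches(frag):
            hits.append(FragmentHit(protein_id, start, frag))
    return hits


def scan_pairs(
    sequence: str,
    acid_set=frozenset("DE"),
    partner_set=frozenset("QR"),
    offset: int = 3,
    region: Optional[tuple] = None,
) -> list:
    """Acid positions j (protein numbering) with seq[j] in acid_set and
    seq[j+offset] in partner_set.

    ``region=(first, last)`` restricts j to that inclusive range; the partner
    may extend past it.  This is the windowless form of the moiety scan used
    to enumerate the i, i+3 charge pairs inside one helix.
    """
    sequence = str(sequence)
    n = len(sequence)
    if region is None:
        first, last = 1, n
    else:
        first, last = region
        if first < 1 or last > n or first > last:
            raise ValueError(f"region {region} out of bounds for length {n}")
    out = []
    for j in range(first, last + 1):
        if j + offset > n:
            break
        if sequence[j - 1] in acid_set and sequence[j - 1 + offset] in partner_set:
            out.append(j)
    return out


def mean_hydrophilicity(sequence: str, scale: Optional[ResidueScale] = None) -> float:
    """Arithmetic mean of per-residue Hopp-Woods hydrophilicity values."""
    if scale is None:
        scale = load_scale("hopp_woods")
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    return float(scale.of(sequence).mean())


def mean_helical_penalty(sequence: str, scale: Optional[ResidueScale] = None) -> float:
    """Mean Pace-Scholtz helix-propensity penalty in kcal/mol (Ala = 0)."""
    if scale is None:
        scale = load_scale("pace_scholtz")
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    return float(scale.of(sequence).mean())


def hydrophobic_moment(
    sequence: str,
    scale: Optional[ResidueScale] = None,
    delta_deg: float = 100.0,
) -> float:
    """Hydrophobic moment per residue on an ideal helical wheel.

    mu_H = (1/N) * sqrt((sum_i H_i sin(d*i))^2 + (sum_i H_i cos(d*i))^2)
    with i = 0..N-1 and d = 100 degrees per residue (ideal alpha helix),
    the normalisation and scale (Fauchere-Pliska) of the HELIQUEST server.
    """
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    if scale is None:
        scale = load_scale("fauchere_pliska")
    h = scale.of(sequence)
    ang = np.deg2rad(delta_deg) * np.arange(len(h))
    s = float(np.dot(h, np.sin(ang)))
    c = float(np.dot(h, np.cos(ang)))
    return math.hypot(s, c) / len(h)


@dataclass
class ScreenReport:
    """Per-fragment moiety hits with scores, in record order then start."""

    hits: list
    pattern: MoietyPattern

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": h.protein_id,
                "start": h.start,
                "end": h.end,
                "fragment": h.sequence,
                "hydrophilicity_mean": h.hydrophilicity_mean,
                "helical_penalty_mean": h.helical_penalty_mean,
                "hydrophobic_moment": h.hydrophobic_moment,
            }
            for h in self.hits
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "protein_id", "start", "end", "fragment",
                "hydrophilicity_mean", "helical_penalty_mean",
                "hydrophobic_moment",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False,
                                   float_format="%.6f")


def screen_proteome(
    records,
    pattern: MoietyPattern = DE4_QR7,
    hydrophilicity_scale: Optional[ResidueScale] = None,
    penalty_scale: Optional[ResidueScale] = None,
    moment_scale: Optional[ResidueScale] = None,
) -> ScreenReport:
    """Scan a multi-record FASTA (path or (id, seq) iterable) for moiety hits.

    Sequences are taken as supplied: callers are responsible for providing
    mature numbering (signal peptides removed) when protein positions matter.
    Duplicate record ids are an error.
    """
    if isinstance(records, (str, Path)):
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(records), "fasta")]
    else:
        records = [(str(i), str(s)) for i, s in records]
    ids = [i for i, _ in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record ids: {dup}")
    if hydrophilicity_scale is None:
        hydrophilicity_scale = load_scale("hopp_woods")
    if penalty_scale is None:
        penalty_scale = load_scale("pace_scholtz")
    if moment_scale is None:
        moment_scale = load_scale("fauchere_pliska")
    hits = []
    for pid, seq in records:
        for h in scan_fragments(seq, pattern, protein_id=pid):
            h.hydrophilicity_mean = mean_hydrophilicity(h.sequence, hydrophilicity_scale)
            h.helical_penalty_mean = mean_helical_penalty(h.sequence, penalty_scale)
            h.hydrophobic_moment = hydrophobic_moment(h.sequence, moment_scale)
            hits.append(h)
    return ScreenReport(hits, pattern)
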