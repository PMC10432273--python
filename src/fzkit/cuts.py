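"""Cleavage-position calling from run-off terminal-position samples and
end-geometry (overhang) classification.

Coordinate convention (the chief off-by-one risk, so stated prominently):
positions are 1-based and mean "cut after the Nth base", with N counted from
the TAM-proximal first protospacer base, on both strands. Run-off polymerases
add one non-templated terminal base at some rate (observed as a terminal A on
the target-strand trace and a terminal T on the NTS trace); samples carrying
that base are corrected back by one position before calling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

DEFAULT_ARTIFACT_BASES = {"TS": "A", "NTS": "T"}
DEFAULT_MODE_FRAC = 0.5


class NoDataError(ValueError):
    """Raised when a strand has no usable samples."""


@dataclass
class CutSiteProfile:
    """Called cut positions per strand.

    ``support`` holds the positions whose post-correction frequency is at
    least ``mode_frac`` of the modal frequency (so bimodal profiles report two
    positions); ``counts`` keeps the full corrected multiset."""

    support: dict[str, list[int]]
    counts: dict[str, Counter] = field(default_factory=dict)
    artifact_trimmed: dict[str, int] = field(default_factory=dict)


def call_cut_positions(
    samples: pd.DataFrame,
    artifact_bases: dict[str, str] | None = None,
    mode_frac: float = DEFAULT_MODE_FRAC,
) -> CutSiteProfile:
    """Call per-strand cut positions from a run-off sample table.

    ``samples`` needs columns ``strand`` (TS/NTS) and ``position``; an
    optional ``terminal_base`` column enables artifact correction: a sample
    whose terminal base equals its strand's artifact base is treated as a
    non-templated addition and decremented by one position.
    """
    artifact_bases = artifact_bases or DEFAULT_ARTIFACT_BASES
    if samples.empty:
        raise NoDataError("no run-off samples")
    if not 0 < mode_frac <= 1:
        raise ValueError("mode_frac must be in (0, 1]")
    support: dict[str, list[int]] = {}
    counts: dict[str, Counter] = {}
    trimmed: dict[str, int] = {}
    has_base = "terminal_base" in samples.columns
    for strand, grp in samples.groupby("strand"):
        strand = str(strand)
        pos = grp["position"].astype(int)
        if has_base:
            is_artifact = (grp["terminal_base"].astype(str).str.upper()
                           == artifact_bases.get(strand, "").upper())
        else:
            is_artifact = pd.Series(False, index=grp.index)
        corrected = pos - is_artifact.astype(int)
        corrected = corrected[corrected >= 1]
        if corrected.empty:
            raise NoDataError(f"no usable samples on strand {strand}")
        c = Counter(corrected.tolist())
        modal = max(c.values())
        support[strand] = sorted(p for p, n in c.items()
                                 if n >= mode_frac * modal)
        counts[strand] = c
        trimmed[strand] = int(is_artifact.sum())
    return CutSiteProfile(support, counts, trimmed)


@dataclass
class OverhangCall:
    end_type: str  # five_prime_overhang | blunt | three_prime_overhang | mixed
    overhang_range: tuple[int, int]  # nt; (0, 0) iff blunt
    ts_positions: list[int]
    nts_positions: list[int]


def classify_overhang(profile: CutSiteProfile) -> OverhangCall:
    """Classify the double-strand end geometry from called cut positions.

    With t = TS positions and n = NTS positions (protospacer coordinates):
    min(t) > max(n) gives a 5' overhang of [min(t)-max(n), max(t)-min(n)] nt;
    identical singletons give blunt; max(t) < min(n) gives a 3' overhang of
    [min(n)-max(t), max(n)-min(t)] nt; anything else is mixed."""
    t = sorted(profile.support.get("TS", []))
    n = sorted(profile.support.get("NTS", []))
    if not t or not n:
        raise NoDataError("both strands need called positions")
    if min(t) > max(n):
        rng = (min(t) - max(n), max(t) - min(n))
        return OverhangCall("five_prime_overhang", rng, t, n)
    if t == n and len(t) == 1:
        return OverhangCall("blunt", (0, 0), t, n)
    if max(t) < min(n):
        rng = (min(n) - max(t), max(n) - min(t))
        return OverhangCall("three_prime_overhang", rng, t, n)
    return OverhangCall("mixed", (0, max(max(t), max(n)) - min(min(t),
                                                              min(n))), t, n)
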