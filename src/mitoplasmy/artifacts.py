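"""Sequence-context artifact flagging for platform error hotspots.

Deep sequencing on the Illumina platform produces recurrent spurious A>C
heteroplasmic calls at positions sharing a sequence-context motif: a run of
at least two A's ending at the called position, immediately followed by at
least two C's (e.g. the context ``ataaaAccccc``). Calls matching the motif,
or matching a curated blacklist of positions that failed orthogonal
validation, are *flagged*, never deleted — downstream burden statistics
exclude flagged calls by default, but the evidence stays inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

from .calling import VariantCall
from .reference import MitoReference, context_window


class ArtifactError(ValueError):
    pass


@dataclass(frozen=True)
class HotspotFlag:
    position: int
    reason: str  # motif_AC | blacklist
    context: str


@dataclass(frozen=True)
class BlacklistEntry:
    position: int
    ref: str
    alt: str
    reason: str = "blacklist"


def is_ac_hotspot(
    ref: MitoReference, position: int, ref_base: str, alt_base: str
) -> bool:
    """True iff an A>C call sits in a >=2A-then->=2C reference context.

    The A-run is counted inclusive of the called position itself (so a
    context like ``aAcc`` qualifies), and the two C's must immediately
    follow the position. Windows wrap circularly around the origin.
    """
    if ref_base.upper() != "A" or alt_base.upper() != "C":
        return False
    if ref.base(position) != "A":
        return False
    # run of A's ending at `position`, including it
    if ref.base(position - 1) != "A":
        return False
    return ref.base(position + 1) == "C" and ref.base(position + 2) == "C"


def motif_positions(ref: MitoReference) -> list[int]:
    """All positions where an A>C call would match the hotspot motif."""
    return [
        p for p in range(1, len(ref) + 1) if is_ac_hotspot(ref, p, ref.base(p), "C")
    ]


def load_blacklist(path: str | Path | None = None) -> list[BlacklistEntry]:
    """Blacklist TSV (position, ref, alt[, reason]); default is packaged."""
    if path is None:
        with resources.as_file(
            resources.files("mitoplasmy.data") / "hotspot_blacklist.tsv"
        ) as p:
            return load_blacklist(p)
    entries: list[BlacklistEntry] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("position\t"):
            continue
        fields = line.split("\t")
        if len(fields) not in (3, 4):
            raise ArtifactError(f"{path}:{lineno}: expected 3 or 4 columns")
        try:
            position = int(fields[0])
        except ValueError as exc:
            raise ArtifactError(f"{path}:{lineno}: bad position {fields[0]!r}") from exc
        ref_b, alt_b = fields[1].upper(), fields[2].upper()
        if ref_b not in "ACGT" or alt_b not in "ACGT":
            raise ArtifactError(f"{path}:{lineno}: bad alleles {ref_b}/{alt_b}")
        reason = fields[3] if len(fields) == 4 else "blacklist"
        entries.append(BlacklistEntry(position, ref_b, alt_b, reason))
    return entries


def flag_call(
    call: VariantCall,
    ref: MitoReference,
    blacklist: list[BlacklistEntry],
    flank: int = 5,
) -> HotspotFlag | None:
    """The flag a single call earns, or None. Motif takes precedence."""
    if is_ac_hotspot(ref, call.position, call.ref_base, call.alt):
        return HotspotFlag(
            call.position, "motif_AC", context_window(ref, call.position, flank)
        )
    for entry in blacklist:
        if (
            entry.position == call.position
            and entry.ref == call.ref_base
            and entry.alt == call.alt
        ):
            return HotspotFlag(
                call.position, "blacklist", context_window(ref, call.position, flank)
            )
    return None


def apply_blacklist(
    calls: list[VariantCall],
    ref: MitoReference,
    blacklist: list[BlacklistEntry] | None = None,
) -> tuple[list[tuple[VariantCall, HotspotFlag]], list[VariantCall]]:
    """Split calls into (flagged-with-reason, retained).

    Flagging annotates rather than removes: flagged calls are returned with
    their :class:`HotspotFlag` so they can be written as VCF FILTER values.
    Idempotent and independent of call order.
    """
    if blacklist is None:
        blacklist = load_blacklist()
    flagged: list[tuple[VariantCall, HotspotFlag]] = []
    retained: list[VariantCall] = []
    for call in calls:
        flag = flag_call(call, ref, blacklist)
        if flag is not None:
            flagged.append((call, flag))
        else:
            retained.append(call)
    return flagged, retained
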