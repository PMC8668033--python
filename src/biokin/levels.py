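"""Spine-section level bookkeeping.

Levels (motion segments) are labelled by their two vertebrae, e.g. ``"C5-C6"``,
and ordered cranial to caudal within a section.  The lower (more caudal)
vertebra of each segment carries the triangle baseline.
"""
from __future__ import annotations

from typing import Iterable, Sequence

from .errors import ConfigError

CERVICAL = "cervical"
LUMBAR = "lumbar"

CERVICAL_LEVELS: tuple[str, ...] = ("C2-C3", "C3-C4", "C4-C5", "C5-C6", "C6-C7")
LUMBAR_LEVELS: tuple[str, ...] = ("L1-L2", "L2-L3", "L3-L4", "L4-L5", "L5-S1")

_SECTION_LEVELS = {CERVICAL: CERVICAL_LEVELS, LUMBAR: LUMBAR_LEVELS}


def section_levels(section: str) -> tuple[str, ...]:
    try:
        return _SECTION_LEVELS[section]
    except KeyError:
        raise ConfigError(f"unknown spine section {section!r}") from None


def infer_section(levels: Iterable[str]) -> str:
    """Infer the section from a set of level labels."""
    levels = set(levels)
    if not levels:
        raise ConfigError("no levels supplied")
    for section, known in _SECTION_LEVELS.items():
        if levels <= set(known):
            return section
    raise ConfigError(f"levels {sorted(levels)} match no known spine section")


def ordered_levels(levels: Iterable[str], section: str | None = None) -> tuple[str, ...]:
    """Return the given levels sorted cranial to caudal."""
    levels = list(levels)
    section = section or infer_section(levels)
    order = section_levels(section)
    unknown = set(levels) - set(order)
    if unknown:
        raise ConfigError(f"levels {sorted(unknown)} not in section {section!r}")
    return tuple(lv for lv in order if lv in set(levels))


def level_above(level: str, present: Sequence[str], section: str | None = None) -> str | None:
    """The segment immediately cranial to *level* among *present*, if any."""
    ordered = ordered_levels(present, section)
    idx = ordered.index(level)
    return ordered[idx - 1] if idx > 0 else None


def neighbors(level: str, present: Sequence[str], section: str | None = None) -> tuple[str, ...]:
    """Immediately adjacent segments (cranial then caudal) among *present*."""
    ordered = ordered_levels(present, section)
    idx = ordered.index(level)
    out = []
    if idx > 0:
        out.append(ordered[idx - 1])
    if idx < len(ordered) - 1:
        out.append(ordered[idx + 1])
    return tuple(out)
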