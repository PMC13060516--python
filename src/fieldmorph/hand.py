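"""Canonical hand landmark scheme and dependency hierarchy.

The hand carries 54 landmarks: 22 primary and 32 accessory.

Primary (22): the five digit tips; the distal and proximal
interphalangeal joints of each finger (8); the thumb's interphalangeal
joint (1); the five metacarpophalangeal joints; the palm center on the
palmar and on the dorsal surface (2); and the base of the wrist (1),
which is the anchor.

Accessory (32): width markers at the dorsoventral midline halfway along
each of the 14 digit segments (28, one thumb-side ``_t`` and one
pinky-side ``_p`` per segment, named after the segment's distal primary
landmark, e.g. ``Rdip_t``/``Rdip_p``); the thumb- and pinky-side
junctions between wrist and palm (``wrist_t``/``wrist_p``); and the two
markers spanning the widest part of the palm
(``palmarCenter_t``/``palmarCenter_p``).

The naming table (digit initial + joint abbreviation: ``T I M R P`` ×
``mcp ipj pip dip tip``) is a convention of this package; other landmark
files are accepted as long as names match between the two sets being
aligned.
"""

from __future__ import annotations

from .alignment import DependencyList

#: Digit initials, thumb first.
DIGITS = ("T", "I", "M", "R", "P")
FINGERS = ("I", "M", "R", "P")

ANCHOR = "wrist"


def finger_chain(d: str) -> list[str]:
    """Joint chain of one four-jointed finger, proximal to distal."""
    return [f"{d}mcp", f"{d}pip", f"{d}dip", f"{d}tip"]


def thumb_chain() -> list[str]:
    """Joint chain of the thumb (one interphalangeal joint only)."""
    return ["Tmcp", "Tipj", "Ttip"]


def primary_landmark_names() -> list[str]:
    names = [ANCHOR, "palmarCenter", "dorsalCenter"]
    names += thumb_chain()
    for d in FINGERS:
        names += finger_chain(d)
    return names


def accessory_landmark_names() -> list[str]:
    """Width markers: one ``_t``/``_p`` pair per digit segment (named by
    the segment's distal joint), plus wrist junctions and palm width."""
    names = []
    for chain in [thumb_chain()] + [finger_chain(d) for d in FINGERS]:
        for distal in chain[1:]:  # one segment per joint past the MCP
            names += [f"{distal}_t", f"{distal}_p"]
    names += ["wrist_t", "wrist_p", "palmarCenter_t", "palmarCenter_p"]
    return names


def canonical_dependencies() -> DependencyList:
    """The anatomical chain wrist → MCP → (IP joints) → tip per digit,
    plus the two palm-center segments, in topological order."""
    pairs: list[tuple[str, str]] = [
        (ANCHOR, "palmarCenter"),
        (ANCHOR, "dorsalCenter"),
    ]
    for chain in [thumb_chain()] + [finger_chain(d) for d in FINGERS]:
        prev = ANCHOR
        for joint in chain:
            pairs.append((prev, joint))
            prev = joint
    return DependencyList(root=ANCHOR, pairs=tuple(pairs))
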