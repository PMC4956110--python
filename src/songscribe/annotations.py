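"""Note annotations on the 1-ms frame grid.

An annotation is an ordered list of non-overlapping note intervals, each a
half-open ``[onset, offset)`` pair of frame indices plus a class label.
Annotations round-trip through tab-separated label files (Audacity label-track
dialect: onset seconds, offset seconds, label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["Note", "Annotation", "read_label_file", "write_label_file"]

#: Reserved label for non-singing calls (broadband separator vocalizations).
CALL_LABEL = "call"
#: Reserved label for notes that could not be assigned to a class.
UNCLASSIFIABLE_LABEL = "unclassifiable"
#: Reserved label used when serializing bare interval lists (no class known).
INTERVAL_LABEL = "interval"

RESERVED_LABELS = frozenset({CALL_LABEL, UNCLASSIFIABLE_LABEL, INTERVAL_LABEL})


@dataclass(frozen=True)
class Note:
    """One note interval: half-open ``[onset, offset)`` in frames."""

    onset: int
    offset: int
    label: str

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError(f"note offset must exceed onset: {self}")

    @property
    def duration(self) -> int:
        return self.offset - self.onset

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.onset + self.offset)


@dataclass
class Annotation:
    """Ordered, non-overlapping notes over a timeline of ``timeline_length`` frames."""

    notes: list[Note]
    timeline_length: int
    frame_ms: float = 1.0

    def __post_init__(self) -> None:
        self.notes = sorted(self.notes, key=lambda n: (n.onset, n.offset))
        prev_off = 0
        for n in self.notes:
            if n.onset < prev_off:
                raise ValueError(f"overlapping notes at frame {n.onset}")
            prev_off = n.offset
        if self.notes and self.notes[-1].offset > self.timeline_length:
            raise ValueError("note extends past the timeline")

    def __len__(self) -> int:
        return len(self.notes)

    def __iter__(self):
        return iter(self.notes)

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.notes]

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Silent gaps between consecutive notes (excludes leading/trailing silence)."""
        return [
            (a.offset, b.onset)
            for a, b in zip(self.notes[:-1], self.notes[1:])
            if b.onset > a.offset
        ]

    def note_mask(self):
        """Boolean per-frame mask, True inside notes."""
        import numpy as np

        mask = np.zeros(self.timeline_length, dtype=bool)
        for n in self.notes:
            mask[n.onset : n.offset] = True
        return mask

    def relabeled(self, mapping: dict[str, str]) -> "Annotation":
        notes = [
            Note(n.onset, n.offset, mapping.get(n.label, n.label)) for n in self.notes
        ]
        return Annotation(notes, self.timeline_length, self.frame_ms)


def read_label_file(path: str | Path, timeline_length: int | None = None,
                    frame_ms: float = 1.0) -> Annotation:
    """Read a tab-separated label file (onset s, offset s, label) into an Annotation.

    If ``timeline_length`` is omitted it is taken as the last offset.
    """
    notes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        on_s, off_s, label = line.split("\t")
        onset = int(round(float(on_s) * 1000.0 / frame_ms))
        offset = int(round(float(off_s) * 1000.0 / frame_ms))
        notes.append(Note(onset, offset, label))
    if timeline_length is None:
        timeline_length = max((n.offset for n in notes), default=0)
    return Annotation(notes, timeline_length, frame_ms)


def write_label_file(path: str | Path, ann: Annotation) -> None:
    lines = [
        f"{n.onset * ann.frame_ms / 1000.0:.6f}\t{n.offset * ann.frame_ms / 1000.0:.6f}\t{n.label}"
        for n in ann.notes
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def intervals_to_annotation(intervals: Sequence[tuple[int, int]],
                            timeline_length: int,
                            labels: Iterable[str] | None = None,
                            frame_ms: float = 1.0) -> Annotation:
    """Wrap bare ``[onset, offset)`` intervals as an Annotation.

    ``labels`` defaults to the reserved interval label for every note.
    """
    if labels is None:
        labels = [INTERVAL_LABEL] * len(intervals)
    notes = [Note(a, b, lab) for (a, b), lab in zip(intervals, labels)]
    return Annotation(notes, timeline_length, frame_ms)
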