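"""Reading and writing the study's external artifacts.

Covers WAV audio (RIFF PCM 16/24/32-bit and IEEE float), Praat TextGrid
interval annotations (long and short text dialects, UTF-8/UTF-16), and the
study manifest (YAML or JSON) that assigns recordings to participants,
tasks, phases and visits.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "AnnotationTier",
    "RecordingEntry",
    "StudyManifest",
    "TASK_LABELS",
    "PHASES",
    "FormatError",
    "EmptyAudioError",
    "AnnotationError",
    "ManifestError",
    "read_wav",
    "write_wav",
    "read_textgrid",
    "write_textgrid",
    "load_manifest",
]

TASK_LABELS = (
    "sustained",
    "glide_up",
    "glide_down",
    "personalized_sentences",
    "standardized_sentences",
    "passage",
    "picture_description",
    "conversation",
    "ddk",
)

#: Phase order mirrors the study schedule: 3 baseline days, 3 post-treatment
#: days, and three follow-up blocks (1, 4 and 8 weeks after treatment).
PHASES = ("Pre", "Post", "FU1", "FU2", "FU3")
VISITS_PER_PHASE = 3


class FormatError(ValueError):
    """Unsupported or unreadable file format."""


class EmptyAudioError(ValueError):
    """Audio file contains no samples."""


class AnnotationError(ValueError):
    """Malformed or inconsistent interval annotation."""


class ManifestError(ValueError):
    """Invalid study manifest."""


@dataclass
class AudioClip:
    """A mono waveform with its task/session identity.

    ``samples`` are float64 in [-1, 1]; ``sample_rate`` in Hz.
    """

    samples: np.ndarray
    sample_rate: int
    source_path: str = ""
    task_label: str | None = None
    session_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("AudioClip is mono; got multi-dim samples")
        if self.samples.size == 0:
            raise EmptyAudioError("zero-length audio")
        if self.task_label is not None and self.task_label not in TASK_LABELS:
            raise ValueError(f"unknown task label {self.task_label!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def scaled(self, factor: float) -> "AudioClip":
        return AudioClip(self.samples * factor, self.sample_rate,
                         self.source_path, self.task_label, self.session_id)


@dataclass
class AnnotationTier:
    """An interval tier: non-overlapping labelled (start, end) spans in seconds.

    Intervals are half-open [start, end), sorted by start time.
    """

    name: str
    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            [(float(a), float(b), str(lab)) for a, b, lab in self.intervals],
            key=lambda iv: (iv[0], iv[1]),
        )
        for a, b, _ in self.intervals:
            if not a < b:
                raise AnnotationError(f"interval start {a} !< end {b}")
        for prev, cur in zip(self.intervals, self.intervals[1:]):
            if cur[0] < prev[1] - 1e-9:
                raise AnnotationError(
                    f"overlapping intervals in tier {self.name!r}: "
                    f"{prev[:2]} and {cur[:2]}"
                )

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

_INT_SCALE = {np.dtype("int16"): 2 ** 15, np.dtype("int32"): 2 ** 31}


def read_wav(path: str | Path, task_label: str | None = None,
             session_id: str | None = None) -> AudioClip:
    """Read a WAV file into a normalized mono :class:`AudioClip`.

    Stereo files are averaged across channels (dual-mono clinical recordings
    are common). Integer PCM is scaled to [-1, 1]; float data is clipped.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise FormatError(f"cannot read {path.name}: {exc}") from exc
    if data.size == 0:
        raise EmptyAudioError(f"{path.name} contains no samples")
    orig = data.dtype
    if data.ndim == 2:
        data = data.astype(np.float64).mean(axis=1)
    else:
        data = data.astype(np.float64)
    if orig == np.dtype("uint8"):
        data = (data - 128.0) / 128.0
    elif orig in _INT_SCALE:
        data = data / _INT_SCALE[orig]
    else:  # float32/float64
        data = np.clip(data, -1.0, 1.0)
    return AudioClip(data, int(rate), source_path=str(path),
                     task_label=task_label, session_id=session_id)


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(Path(path)), clip.sample_rate, pcm)


# ---------------------------------------------------------------------------
# Praat TextGrid (long and short text dialects)
# ---------------------------------------------------------------------------

def _decode_textgrid(raw: bytes) -> str:
    if raw.startswith(b"\xff\xfe") or raw.startswith(b"\xfe\xff"):
        return raw.decode("utf-16")
    try:
        return raw.decode("utf-8-sig")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


_DECOR = re.compile(r"^\s*(item\s*\[\s*\d*\s*\]:?|intervals\s*\[\s*\d+\s*\]:?|"
                    r"points\s*\[\s*\d+\s*\]:?)\s*$")
_KEYVAL = re.compile(r"^\s*[\w?():\s]+?=\s*(.*)$")


def _tokenize_textgrid(text: str) -> list[tuple[str, int]]:
    """Flatten both TextGrid dialects into a (token, line_no) stream.

    Long-format decoration (``item [1]:`` headers, ``key = value`` prefixes)
    is stripped so the value sequence matches the short format.
    """
    tokens: list[tuple[str, int]] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or _DECOR.match(s):
            continue
        if "<exists>" in s:
            tokens.append(("<exists>", ln))
            continue
        m = _KEYVAL.match(s)
        if m and not (s.startswith('"') and s.endswith('"')):
            s = m.group(1).strip()
            if not s:
                continue
        if s.startswith('"'):
            tokens.append((s[1:-1].replace('""', '"') if s.endswith('"') and len(s) > 1
                           else s[1:], ln))
        else:
            tokens.append((s, ln))
    return tokens


def read_textgrid(path: str | Path) -> list[AnnotationTier]:
    """Parse a TextGrid file into its interval tiers.

    Accepts long and short text dialects, UTF-8 or UTF-16. Point (text)
    tiers are skipped with a warning. Intervals with empty labels — the
    fillers Praat uses to tile a tier — are dropped, so the returned tiers
    contain only annotated spans.
    """
    path = Path(path)
    tokens = _tokenize_textgrid(_decode_textgrid(path.read_bytes()))
    pos = 0

    def take(expect: str | None = None) -> tuple[str, int]:
        nonlocal pos
        if pos >= len(tokens):
            raise AnnotationError(f"{path.name}: truncated file")
        tok = tokens[pos]
        pos += 1
        return tok

    def take_float() -> float:
        tok, ln = take()
        try:
            return float(tok)
        except ValueError:
            raise AnnotationError(
                f"{path.name}: expected a number at line {ln}, got {tok!r}"
            ) from None

    ftype, _ = take()
    if "ooTextFile" not in ftype:
        raise AnnotationError(f"{path.name}: not a TextGrid (missing ooTextFile header)")
    otype, _ = take()
    if "TextGrid" not in otype:
        raise AnnotationError(f"{path.name}: object class is {otype!r}, not TextGrid")
    take_float()  # global xmin
    take_float()  # global xmax
    tok, _ = take()
    if tok != "<exists>":
        raise AnnotationError(f"{path.name}: tiers flag missing")
    n_tiers = int(take_float())

    tiers: list[AnnotationTier] = []
    for _ in range(n_tiers):
        tclass, _ = take()
        tname, _ = take()
        take_float()  # tier xmin
        take_float()  # tier xmax
        n_items = int(take_float())
        if tclass == "IntervalTier":
            intervals = []
            for _ in range(n_items):
                a = take_float()
                b = take_float()
                lab, _ = take()
                if lab.strip():
                    intervals.append((a, b, lab))
            tiers.append(AnnotationTier(tname, intervals))
        elif tclass == "TextTier":
            warnings.warn(f"{path.name}: skipping point tier {tname!r}")
            for _ in range(n_items):
                take_float()
                take()
        else:
            raise AnnotationError(f"{path.name}: unknown tier class {tclass!r}")
    return tiers


def write_textgrid(path: str | Path, tiers: Sequence[AnnotationTier],
                   xmax: float | None = None) -> None:
    """Write interval tiers as a long-format UTF-8 TextGrid.

    Gaps between annotated intervals are filled with empty labels so the
    tier tiles [0, xmax] as Praat expects.
    """
    if xmax is None:
        xmax = max((iv[1] for t in tiers for iv in t.intervals), default=1.0)

    def esc(s: str) -> str:
        return s.replace('"', '""')

    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for ti, tier in enumerate(tiers, start=1):
        filled: list[tuple[float, float, str]] = []
        cursor = 0.0
        for a, b, lab in tier.intervals:
            if a > cursor + 1e-9:
                filled.append((cursor, a, ""))
            filled.append((a, b, lab))
            cursor = b
        if cursor < xmax - 1e-9:
            filled.append((cursor, xmax, ""))
        lines += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f'        name = "{esc(tier.name)}"',
            "        xmin = 0",
            f"        xmax = {xmax:.6f}",
            f"        intervals: size = {len(filled)}",
        ]
        for ii, (a, b, lab) in enumerate(filled, start=1):
            lines += [
                f"        intervals [{ii}]:",
                f"            xmin = {a:.6f}",
                f"            xmax = {b:.6f}",
                f'            text = "{esc(lab)}"',
            ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Study manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingEntry:
    participant_id: str
    task_label: str
    phase: str
    visit_index: int
    trial_index: int
    audio_path: str | None = None
    annotation_path: str | None = None
    syllable_count: int | None = None
    group_syllables: tuple[int, ...] | None = None

    @property
    def session_id(self) -> str:
        return f"{self.phase}-{self.visit_index}"

    def sort_key(self):
        return (self.participant_id, self.task_label,
                PHASES.index(self.phase), self.visit_index, self.trial_index)


@dataclass
class StudyManifest:
    """Validated study description: recordings plus explicit session gaps.

    A *gap* is an expected (participant, task, phase, visit) slot with no
    recording — unequal session counts are data, not errors, so they are
    recorded rather than rejected.
    """

    participants: list[str]
    entries: list[RecordingEntry]
    gaps: list[tuple[str, str, str, int]] = field(default_factory=list)
    base_dir: Path = field(default_factory=Path)

    def for_participant_task(self, participant: str, task: str) -> list[RecordingEntry]:
        return [e for e in self.entries
                if e.participant_id == participant and e.task_label == task]


def load_manifest(path: str | Path, check_files: bool = True) -> StudyManifest:
    """Load and validate a YAML/JSON study manifest.

    Unknown phase or task labels raise :class:`ManifestError`, as do
    duplicate (participant, task, phase, visit, trial) keys. Missing
    (phase, visit) slots for a task a participant otherwise performed are
    returned as explicit gaps. Relative file paths resolve against the
    manifest's directory.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict) or "recordings" not in doc:
        raise ManifestError(f"{path.name}: manifest must map 'recordings' to a list")
    base = path.parent

    entries: list[RecordingEntry] = []
    seen: set[tuple] = set()
    for i, rec in enumerate(doc["recordings"]):
        try:
            entry = RecordingEntry(
                participant_id=str(rec["participant"]),
                task_label=str(rec["task"]),
                phase=str(rec["phase"]),
                visit_index=int(rec["visit"]),
                trial_index=int(rec.get("trial", 1)),
                audio_path=rec.get("audio"),
                annotation_path=rec.get("annotation"),
                syllable_count=(int(rec["syllable_count"])
                                if rec.get("syllable_count") is not None else None),
                group_syllables=(tuple(int(g) for g in rec["group_syllables"])
                                 if rec.get("group_syllables") else None),
            )
        except KeyError as exc:
            raise ManifestError(f"recording #{i}: missing field {exc}") from None
        if entry.phase not in PHASES:
            raise ManifestError(
                f"recording #{i}: unknown phase {entry.phase!r} (expected one of {PHASES})")
        if entry.task_label not in TASK_LABELS:
            raise ManifestError(
                f"recording #{i}: unknown task {entry.task_label!r} "
                f"(expected one of {TASK_LABELS})")
        if not 1 <= entry.visit_index <= VISITS_PER_PHASE:
            raise ManifestError(f"recording #{i}: visit must be 1..{VISITS_PER_PHASE}")
        key = (entry.participant_id, entry.task_label, entry.phase,
               entry.visit_index, entry.trial_index)
        if key in seen:
            raise ManifestError(f"duplicate recording slot {key}")
        seen.add(key)
        if check_files and entry.audio_path is not None:
            p = base / entry.audio_path
            if not p.exists():
                raise ManifestError(f"recording #{i}: audio file not found: {p}")
        if check_files and entry.annotation_path is not None:
            p = base / entry.annotation_path
            if not p.exists():
                raise ManifestError(f"recording #{i}: annotation file not found: {p}")
        entries.append(entry)

    entries.sort(key=RecordingEntry.sort_key)
    participants = doc.get("participants")
    if participants is None:
        participants = sorted({e.participant_id for e in entries})
    else:
        participants = [str(p) for p in participants]

    gaps: list[tuple[str, str, str, int]] = []
    have = {(e.participant_id, e.task_label, e.phase, e.visit_index) for e in entries}
    tasks_by_part: dict[str, set[str]] = {}
    for e in entries:
        tasks_by_part.setdefault(e.participant_id, set()).add(e.task_label)
    for part in participants:
        for task in sorted(tasks_by_part.get(part, set())):
            for phase in PHASES:
                for visit in range(1, VISITS_PER_PHASE + 1):
                    if (part, task, phase, visit) not in have:
                        gaps.append((part, task, phase, visit))
    return StudyManifest(participants=participants, entries=entries,
                         gaps=gaps, base_dir=base)
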