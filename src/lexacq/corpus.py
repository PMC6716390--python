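"""Child-directed-speech corpora as tokenized utterances.

The on-disk format is a deliberately minimal "CHAT-lite" dialect: UTF-8
text, one utterance per line, ``SPEAKER<TAB>token token ...``.  Speaker
codes are free-form strings; anything other than the configured child
codes is treated as an adult speaker.  Morphological tiers, timestamps
and other full-CHAT machinery are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

ADULT = "adult"
CHILD = "child"

#: speaker codes conventionally used for target children
_CHILD_CODES = frozenset({"CHI", "CHILD"})


@dataclass(frozen=True)
class Utterance:
    """One utterance: a speaker role and a nonempty ordered token list."""

    speaker_role: str
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.speaker_role not in (ADULT, CHILD):
            raise ValueError(f"speaker_role must be {ADULT!r} or {CHILD!r}, "
                             f"got {self.speaker_role!r}")
        if len(self.tokens) == 0:
            raise ValueError("utterance must contain at least one token")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Corpus:
    """Ordered collection of utterances for one language."""

    utterances: list[Utterance] = field(default_factory=list)
    language: str | None = None

    def __len__(self) -> int:
        return len(self.utterances)

    def __iter__(self) -> Iterator[Utterance]:
        return iter(self.utterances)

    def filter_speaker(self, role: str) -> "Corpus":
        return Corpus([u for u in self.utterances if u.speaker_role == role],
                      language=self.language)

    @property
    def n_tokens(self) -> int:
        return sum(len(u) for u in self.utterances)


def parse_chat_lite(lines: Iterable[str], *, language: str | None = None,
                    child_codes: frozenset[str] = _CHILD_CODES) -> Corpus:
    """Parse CHAT-lite lines into a :class:`Corpus`.

    Blank lines are skipped.  A line without a tab separator is malformed.
    """
    utterances = []
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if "\t" not in line:
            raise ValueError(f"line {i}: expected 'SPEAKER<TAB>tokens', got {line!r}")
        speaker, text = line.split("\t", 1)
        tokens = tuple(text.split())
        if not tokens:
            raise ValueError(f"line {i}: utterance has no tokens")
        role = CHILD if speaker.strip().upper() in child_codes else ADULT
        utterances.append(Utterance(role, tokens))
    return Corpus(utterances, language=language)


def read_corpus(path: str | Path, *, language: str | None = None) -> Corpus:
    """Read a CHAT-lite corpus file."""
    with open(path, encoding="utf-8") as fh:
        return parse_chat_lite(fh, language=language)


def write_corpus(corpus: Corpus, path: str | Path,
                 speaker_codes: dict[str, str] | None = None) -> None:
    """Write a corpus in CHAT-lite format (adult -> ``ADU``, child -> ``CHI``)."""
    codes = speaker_codes or {ADULT: "ADU", CHILD: "CHI"}
    with open(path, "w", encoding="utf-8") as fh:
        for u in corpus:
            fh.write(f"{codes[u.speaker_role]}\t{' '.join(u.tokens)}\n")
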