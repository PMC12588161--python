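"""Message corpora and social-media tokenization.

The unit of observation is a short, timestamped status update.  A
:class:`MessageCorpus` groups messages by author so that downstream feature
extraction can operate per user.  Tokenization is rule based and tuned to
social-media text: emoticons (``:)``, ``:(``), punctuation runs (``!!!``) and
contractions (``can't``) survive as single tokens, because such tokens carry
trait signal; URLs and @-mentions are collapsed to sentinel tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Message",
    "MessageCorpus",
    "EmptyCorpusError",
    "tokenize",
    "filter_users_by_word_count",
    "URL_TOKEN",
    "MENTION_TOKEN",
]

URL_TOKEN = "<url>"
MENTION_TOKEN = "<user>"


class EmptyCorpusError(ValueError):
    """Raised when a filtering step removes every user from a corpus."""


@dataclass(frozen=True)
class Message:
    user_id: str
    message_id: str
    created_at: datetime | None
    text: str


_TOKEN_RE = re.compile(
    r"""
    (?P<url>(?:https?://|www\.)\S+)
  | (?P<mention>@\w+)
  | (?P<hashtag>\#\w+)
  | (?P<emoticon><3|</3|[<>]?[:;=][\-o'\*]?[\)\(\]\[dpo/\\|3\*]+)
  | (?P<word>[a-z0-9_]+(?:['’][a-z0-9_]+)*)
  | (?P<punct>[^\w\s]+)
    """,
    re.VERBOSE,
)


def tokenize(text: str) -> list[str]:
    """Split ``text`` into lowercased social-media tokens.

    Emoticons, hashtags, punctuation runs and internal apostrophes are
    preserved; URLs become ``<url>`` and @-mentions become ``<user>``.
    Empty input yields an empty list.
    """
    tokens: list[str] = []
    for m in _TOKEN_RE.finditer(text.lower()):
        if m.lastgroup == "url":
            tokens.append(URL_TOKEN)
        elif m.lastgroup == "mention":
            tokens.append(MENTION_TOKEN)
        else:
            tokens.append(m.group())
    return tokens


@dataclass
class MessageCorpus:
    """An ordered collection of messages with a per-user index."""

    messages: list[Message]
    _user_index: dict[str, list[Message]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, list[Message]] = {}
        seen: set[str] = set()
        for msg in self.messages:
            if msg.message_id in seen:
                raise ValueError(f"duplicate message_id: {msg.message_id!r}")
            seen.add(msg.message_id)
            index.setdefault(msg.user_id, []).append(msg)
        self._user_index = index

    @property
    def user_ids(self) -> list[str]:
        return list(self._user_index)

    @property
    def n_users(self) -> int:
        return len(self._user_index)

    def messages_for(self, user_id: str) -> list[Message]:
        return self._user_index[user_id]

    def __len__(self) -> int:
        return len(self.messages)

    def __iter__(self) -> Iterator[Message]:
        return iter(self.messages)

    def iter_user_tokens(self) -> Iterator[tuple[str, list[list[str]]]]:
        """Yield ``(user_id, token lists per message)`` in user order."""
        for uid, msgs in self._user_index.items():
            yield uid, [tokenize(m.text) for m in msgs]

    def subset_users(self, user_ids: Iterable[str]) -> "MessageCorpus":
        keep = set(user_ids)
        return MessageCorpus([m for m in self.messages if m.user_id in keep])

    def subset_time(
        self, start: datetime, end: datetime
    ) -> "MessageCorpus":
        """Messages with ``start <= created_at < end`` (half-open)."""
        return MessageCorpus(
            [
                m
                for m in self.messages
                if m.created_at is not None and start <= m.created_at < end
            ]
        )

    def word_counts(self) -> dict[str, int]:
        """Total token count per user."""
        return {
            uid: sum(len(toks) for toks in msg_tokens)
            for uid, msg_tokens in self.iter_user_tokens()
        }


def filter_users_by_word_count(
    corpus: MessageCorpus, min_words: int = 1000
) -> MessageCorpus:
    """Drop users whose total token count is below ``min_words``.

    The threshold is inclusive: a user with exactly ``min_words`` tokens is
    retained.  Raises :class:`EmptyCorpusError` if nobody survives.
    """
    if min_words < 0:
        raise ValueError("min_words must be non-negative")
    counts = corpus.word_counts()
    keep = [uid for uid, c in counts.items() if c >= min_words]
    if not keep:
        raise EmptyCorpusError(
            f"no user has at least {min_words} words; corpus is empty"
        )
    if len(keep) == corpus.n_users:
        return corpus
    return corpus.subset_users(keep)
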