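"""Reading and writing dependency-annotated corpora.

Two on-disk dialects are supported:

* a 7-column tab/comma-separated table (sentence id, dependent order,
  dependent form, dependent POS, governor order, governor form, relation),
  optionally with an extra governor-POS column which is ignored;
* standard 10-column CoNLL-U.

Both readers produce the same in-memory :class:`Treebank`. Word forms are
NFC-normalized and whitespace-stripped; no case folding is applied.
Networks can be exported in Pajek ``.net`` format. All paths may be plain
or gzip-compressed (``.gz``).
"""

from __future__ import annotations

import gzip
import io
import unicodedata
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from synnet.errors import ParseError, ValidationError

#: POS tags that mark punctuation tokens in common tag sets.
DEFAULT_PUNCT_TAGS = frozenset({"wp", "PU", "PUNCT"})

#: Relation label used for the sentence root in the tabular dialect.
ROOT_RELATION = "HED"

#: Placeholder used for the governor form/POS of root rows.
ROOT_PLACEHOLDER = "/"

MODALITIES = ("written", "oral")
LEVELS = (1, 2, 3, 4, "native")


def _normalize_form(form: str) -> str:
    return unicodedata.normalize("NFC", form).strip()


@dataclass(frozen=True)
class Token:
    """One annotated word: a dependent pointing at its governor.

    ``governor_order`` is the 1-based sentence position of the governor;
    0 marks the sentence root, which carries no dependency edge.
    """

    order: int
    form: str
    pos: str = "_"
    governor_order: int = 0
    relation: str = ROOT_RELATION
    is_punct: bool = False

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError(f"token order must be >= 1, got {self.order}")
        if self.governor_order < 0:
            raise ValidationError(
                f"governor order must be >= 0, got {self.governor_order}"
            )
        if self.governor_order == self.order:
            raise ValidationError(
                f"token {self.order} ({self.form!r}) governs itself"
            )

    @property
    def is_root(self) -> bool:
        return self.governor_order == 0


@dataclass(frozen=True)
class Sentence:
    """An ordered sequence of tokens forming one annotated sentence."""

    sentence_id: str
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        self.validate()

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    def validate(self) -> None:
        n = len(self.tokens)
        if n == 0:
            raise ValidationError(f"sentence {self.sentence_id!r} has no tokens")
        orders = [t.order for t in self.tokens]
        if orders != list(range(1, n + 1)):
            raise ValidationError(
                f"sentence {self.sentence_id!r}: token orders {orders} "
                f"are not consecutive 1..{n}"
            )
        for tok in self.tokens:
            if tok.governor_order > n:
                raise ValidationError(
                    f"sentence {self.sentence_id!r}: token {tok.order} "
                    f"({tok.form!r}) has governor order {tok.governor_order} "
                    f"outside 0..{n}"
                )
        roots = [t for t in self.tokens if t.is_root]
        if not roots:
            warnings.warn(
                f"sentence {self.sentence_id!r} has no root token", stacklevel=2
            )
        elif len(roots) > 1:
            warnings.warn(
                f"sentence {self.sentence_id!r} has {len(roots)} root tokens "
                "(fragmentary annotation tolerated)",
                stacklevel=2,
            )

    @property
    def root_count(self) -> int:
        return sum(1 for t in self.tokens if t.is_root)

    def governor_of(self, token: Token) -> Token | None:
        """Return the governing token, or None for root rows."""
        if token.is_root:
            return None
        return self.tokens[token.governor_order - 1]


@dataclass(frozen=True)
class CorpusMeta:
    """Identity of a corpus within a study: modality, level and a label."""

    modality: str = "written"
    level: int | str = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        if self.level not in LEVELS:
            raise ValidationError(
                f"level must be one of {LEVELS}, got {self.level!r}"
            )


@dataclass
class Treebank:
    """An ordered collection of sentences plus corpus metadata."""

    sentences: list[Sentence] = field(default_factory=list)
    meta: CorpusMeta = field(default_factory=CorpusMeta)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[Sentence]:
        return iter(self.sentences)

    @property
    def token_count(self) -> int:
        return sum(len(s) for s in self.sentences)

    def tokens(self) -> Iterator[tuple[Sentence, Token]]:
        for sent in self.sentences:
            for tok in sent.tokens:
                yield sent, tok

    def with_meta(self, meta: CorpusMeta) -> "Treebank":
        return Treebank(sentences=list(self.sentences), meta=meta)


# ---------------------------------------------------------------------------
# file helpers


def _open_text(path: str | Path, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")  # type: ignore[return-value]
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# tabular dialect


def read_dependency_table(
    path: str | Path,
    *,
    sep: str | None = "\t",
    punct_tags: Iterable[str] = DEFAULT_PUNCT_TAGS,
    meta: CorpusMeta | None = None,
) -> Treebank:
    """Read the 7-column tabular annotation dialect.

    Columns: sentence id, dependent order, dependent form, dependent POS,
    governor order, governor form (placeholder for roots), relation. An
    optional 8th governor-POS column is tolerated and ignored. Rows must be
    grouped by sentence id; ``#`` lines are comments. The governor-form
    column is cross-checked against the token found at the governor order
    and mismatches are reported as warnings, never silently corrected.
    """
    punct_tags = frozenset(punct_tags)
    rows: list[tuple[int, list[str]]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split(sep) if sep else line.split()
            if len(parts) not in (7, 8):
                raise ParseError(
                    f"{path}: line {lineno}: expected 7 or 8 columns, "
                    f"got {len(parts)}"
                )
            rows.append((lineno, parts))
    if not rows:
        raise ParseError(f"{path}: no sentences")

    sentences: list[Sentence] = []
    current_id: str | None = None
    current: list[tuple[int, list[str]]] = []

    def flush() -> None:
        if current_id is None:
            return
        sentences.append(_table_rows_to_sentence(current_id, current, punct_tags, path))

    for lineno, parts in rows:
        sid = parts[0].strip()
        if sid != current_id:
            flush()
            current_id = sid
            current = []
        current.append((lineno, parts))
    flush()
    return Treebank(sentences=sentences, meta=meta or CorpusMeta())


def _table_rows_to_sentence(
    sentence_id: str,
    rows: Sequence[tuple[int, Sequence[str]]],
    punct_tags: frozenset[str],
    path: str | Path,
) -> Sentence:
    tokens: list[Token] = []
    gov_forms: list[tuple[int, int, str]] = []  # (lineno, governor order, form)
    for lineno, parts in rows:
        try:
            order = int(parts[1])
            gov_order = int(parts[4])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-integer order: {exc}")
        form = _normalize_form(parts[2])
        pos = parts[3].strip()
        gov_form = _normalize_form(parts[5])
        relation = parts[-1].strip()
        if (relation == ROOT_RELATION) != (gov_order == 0):
            raise ValidationError(
                f"{path}: line {lineno}: sentence {sentence_id!r}: relation "
                f"{relation!r} inconsistent with governor order {gov_order}"
            )
        try:
            tokens.append(
                Token(
                    order=order,
                    form=form,
                    pos=pos,
                    governor_order=gov_order,
                    relation=relation,
                    is_punct=pos in punct_tags,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}")
        if gov_order > 0 and gov_form not in ("", ROOT_PLACEHOLDER, "_"):
            gov_forms.append((lineno, gov_order, gov_form))
    try:
        sent = Sentence(sentence_id=sentence_id, tokens=tuple(tokens))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}")
    for lineno, gov_order, gov_form in gov_forms:
        actual = sent.tokens[gov_order - 1].form
        if actual != gov_form:
            warnings.warn(
                f"{path}: line {lineno}: governor form column says "
                f"{gov_form!r} but token {gov_order} is {actual!r}",
                stacklevel=3,
            )
    return sent


def write_dependency_table(treebank: Treebank, path: str | Path, *, sep: str = "\t") -> None:
    """Serialize a treebank in the 7-column tabular dialect."""
    with _open_text(path, "wt") as fh:
        for sent in treebank:
            for tok in sent:
                gov = sent.governor_of(tok)
                fh.write(
                    sep.join(
                        (
                            sent.sentence_id,
                            str(tok.order),
                            tok.form,
                            tok.pos,
                            str(tok.governor_order),
                            gov.form if gov is not None else ROOT_PLACEHOLDER,
                            tok.relation,
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# CoNLL-U


def read_conllu(
    path: str | Path,
    *,
    punct_tags: Iterable[str] = DEFAULT_PUNCT_TAGS,
    meta: CorpusMeta | None = None,
) -> Treebank:
    """Read a 10-column CoNLL-U file.

    HEAD maps to governor order, DEPREL to relation, UPOS to POS; a UPOS in
    the punctuation tag set flags the token as punctuation. Multiword-token
    ranges (``1-2``) and empty nodes (``1.1``) are skipped. Non-HED root
    labels are tolerated (a warning is emitted once per file).
    """
    punct_tags = frozenset(punct_tags)
    sentences: list[Sentence] = []
    current: list[Token] = []
    current_id: str | None = None
    foreign_root_labels: set[str] = set()

    def flush() -> None:
        nonlocal current, current_id
        if current:
            sid = current_id or f"s{len(sentences) + 1}"
            sentences.append(Sentence(sentence_id=sid, tokens=tuple(current)))
        current = []
        current_id = None

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key.strip() == "sent_id":
                    current_id = value.strip()
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ParseError(
                    f"{path}: line {lineno}: expected 10 columns, got {len(cols)}"
                )
            tok_id = cols[0]
            if "-" in tok_id or "." in tok_id:
                continue  # multiword range / empty node
            try:
                order = int(tok_id)
                head = int(cols[6])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer ID or HEAD "
                    f"({tok_id!r}, {cols[6]!r})"
                )
            pos = cols[3]
            relation = cols[7]
            if head == 0 and relation != ROOT_RELATION:
                foreign_root_labels.add(relation)
            try:
                current.append(
                    Token(
                        order=order,
                        form=_normalize_form(cols[1]),
                        pos=pos,
                        governor_order=head,
                        relation=relation,
                        is_punct=pos in punct_tags,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}")
    flush()
    if not sentences:
        raise ParseError(f"{path}: no sentences")
    if foreign_root_labels:
        warnings.warn(
            f"{path}: root rows use label(s) {sorted(foreign_root_labels)} "
            f"instead of {ROOT_RELATION!r}",
            stacklevel=2,
        )
    return Treebank(sentences=sentences, meta=meta or CorpusMeta())


def write_conllu(treebank: Treebank, path: str | Path) -> None:
    """Serialize a treebank as 10-column CoNLL-U."""
    with _open_text(path, "wt") as fh:
        for sent in treebank:
            fh.write(f"# sent_id = {sent.sentence_id}\n")
            for tok in sent:
                fh.write(
                    "\t".join(
                        (
                            str(tok.order),
                            tok.form,
                            "_",
                            tok.pos,
                            "_",
                            "_",
                            str(tok.governor_order),
                            tok.relation,
                            "_",
                            "_",
                        )
                    )
                    + "\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# Pajek export


def read_pajek(path: str | Path):
    """Read a Pajek ``.net`` file written by :func:`write_pajek`.

    Only the ``*Vertices`` / ``*Edges`` subset emitted by this package is
    supported; edge weights are interpreted as multiplicities.
    """
    from synnet.network import SyntacticNetwork  # local import, avoids cycle

    net = SyntacticNetwork()
    labels: dict[int, str] = {}
    section = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                section = "vertices"
                continue
            if low.startswith("*edges") or low.startswith("*arcs"):
                section = "edges"
                continue
            if section == "vertices":
                num, _, rest = line.partition(" ")
                label = rest.strip().strip('"')
                labels[int(num)] = label
                net.add_vertex(label)
            elif section == "edges":
                parts = line.split()
                if len(parts) < 2:
                    raise ParseError(f"{path}: line {lineno}: bad edge line")
                i, j = int(parts[0]), int(parts[1])
                w = int(float(parts[2])) if len(parts) > 2 else 1
                net.add_edge(labels[i], labels[j], count=w)
            else:
                raise ParseError(f"{path}: line {lineno}: content outside section")
    if net.N == 0:
        raise ParseError(f"{path}: no vertices")
    return net


def write_pajek(network, path: str | Path) -> None:
    """Write a network as a Pajek ``.net`` file.

    Vertices are numbered 1..N in the network's stable vertex order; edge
    lines carry the dependency-instance multiplicity as weight.
    """
    if network.N == 0:
        raise ValidationError("cannot export an empty network")
    index = {v: i + 1 for i, v in enumerate(network.vertices)}
    with _open_text(path, "wt") as fh:
        fh.write(f"*Vertices {network.N}\n")
        for v, i in index.items():
            fh.write(f'{i} "{v}"\n')
        fh.write("*Edges\n")
        for (u, v), mult in network.edges():
            fh.write(f"{index[u]} {index[v]} {mult}\n")
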