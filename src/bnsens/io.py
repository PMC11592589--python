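"""Interchange I/O: BIF 0.15 network files, CSV record datasets and
two-column tag maps.

BIF is the plain-text Bayesian interchange dialect that most BN tools read
and write.  Variable and state declaration order is preserved exactly, CPT
columns are written row-major over declared parent state orders, and
probabilities are serialized with 17 significant digits so a write/read
round trip is exact.  The variable ``tag`` is carried in a BIF ``property``
line (``property tag lab ;``) and ignored by tools that do not know it.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .learning import MISSING, RecordDataset
from .network import CPT, Network, Variable

__all__ = [
    "read_bif",
    "write_bif",
    "read_dataset",
    "write_dataset",
    "read_tags",
    "write_tags",
    "read_normals",
    "write_normals",
    "BIFParseError",
]

_WORD = re.compile(r"[A-Za-z0-9_.+\-]+")


class BIFParseError(ValueError):
    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# tokenizer


def _tokenize(text: str):
    """Yield (token, line) pairs; comments (// and /* */) are stripped."""
    text = re.sub(r"/\*.*?\*/", lambda m: re.sub(r"[^\n]", " ", m.group()), text, flags=re.S)
    text = re.sub(r"//[^\n]*", "", text)
    tokens = []
    for ln, line in enumerate(text.splitlines(), start=1):
        pos = 0
        while pos < len(line):
            ch = line[pos]
            if ch.isspace():
                pos += 1
                continue
            if ch in "{}();|,[]":
                tokens.append((ch, ln))
                pos += 1
                continue
            m = _WORD.match(line, pos)
            if not m:
                raise BIFParseError(f"unexpected character {ch!r}", ln)
            tokens.append((m.group(), ln))
            pos = m.end()
    return tokens


class _Stream:
    def __init__(self, tokens):
        self.tokens = tokens
        self.i = 0

    @property
    def line(self):
        idx = min(self.i, len(self.tokens) - 1)
        return self.tokens[idx][1] if self.tokens else 0

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def next(self):
        if self.i >= len(self.tokens):
            raise BIFParseError("unexpected end of file")
        tok = self.tokens[self.i]
        self.i += 1
        return tok[0]

    def expect(self, tok):
        got = self.next()
        if got != tok:
            raise BIFParseError(f"expected {tok!r}, got {got!r}", self.line)
        return got


# ---------------------------------------------------------------------------
# reading


def read_bif(path) -> Network:
    """Parse a BIF 0.15 file into a :class:`Network`."""
    with open(path) as fh:
        text = fh.read()
    s = _Stream(_tokenize(text))

    variables = []
    seen = {}
    cpt_specs = []

    while s.peek() is not None:
        kw = s.next()
        if kw == "network":
            s.next()  # name
            _skip_block(s)
        elif kw == "variable":
            v = _parse_variable(s)
            if v.name in seen:
                raise BIFParseError(f"duplicate variable declaration {v.name!r}", s.line)
            seen[v.name] = v
            variables.append(v)
        elif kw == "probability":
            cpt_specs.append(_parse_probability(s))
        else:
            raise BIFParseError(f"unexpected keyword {kw!r}", s.line)

    cpts = []
    have_cpt = set()
    for owner, parents, rows, table_row, line in cpt_specs:
        if owner not in seen:
            raise BIFParseError(f"probability block for undeclared variable {owner!r}", line)
        if owner in have_cpt:
            raise BIFParseError(f"duplicate probability block for {owner!r}", line)
        have_cpt.add(owner)
        for p in parents:
            if p not in seen:
                raise BIFParseError(
                    f"probability block of {owner!r}: undeclared parent {p!r}", line
                )
        k = seen[owner].n_states
        sizes = [seen[p].n_states for p in parents]
        n_cfg = int(np.prod(sizes)) if parents else 1
        table = np.empty((n_cfg, k))
        if table_row is not None:
            if len(table_row) != n_cfg * k:
                raise BIFParseError(
                    f"variable {owner!r}: table lists {len(table_row)} values, "
                    f"expected {n_cfg * k}", line,
                )
            table[:] = np.asarray(table_row).reshape(n_cfg, k)
        else:
            if len(rows) != n_cfg:
                raise BIFParseError(
                    f"variable {owner!r}: {len(rows)} CPT rows do not match "
                    f"{n_cfg} parent configurations", line,
                )
            filled = set()
            strides = np.ones(len(parents), dtype=np.int64)
            for j in range(len(parents) - 2, -1, -1):
                strides[j] = strides[j + 1] * sizes[j + 1]
            for config, values, rline in rows:
                if len(config) != len(parents):
                    raise BIFParseError(
                        f"variable {owner!r}: configuration arity mismatch", rline
                    )
                idx = 0
                for j, (p, st) in enumerate(zip(parents, config)):
                    try:
                        idx += seen[p].state_index(st) * strides[j]
                    except KeyError as e:
                        raise BIFParseError(str(e), rline) from None
                if idx in filled:
                    raise BIFParseError(
                        f"variable {owner!r}: duplicate configuration {config}", rline
                    )
                if len(values) != k:
                    raise BIFParseError(
                        f"variable {owner!r}: {len(values)} probabilities for "
                        f"{k} states", rline,
                    )
                filled.add(idx)
                table[idx] = values
            if len(filled) != n_cfg:
                raise BIFParseError(
                    f"variable {owner!r}: only {len(filled)} of {n_cfg} "
                    f"configurations specified", line,
                )
        cpts.append(CPT(owner, tuple(parents), table))

    missing = [v.name for v in variables if v.name not in have_cpt]
    if missing:
        raise BIFParseError(f"variables without probability blocks: {missing}")
    return Network(variables, cpts)


def _skip_block(s: _Stream):
    s.expect("{")
    depth = 1
    while depth:
        tok = s.next()
        if tok == "{":
            depth += 1
        elif tok == "}":
            depth -= 1


def _parse_variable(s: _Stream) -> Variable:
    name = s.next()
    s.expect("{")
    states, tag = None, "untagged"
    while True:
        tok = s.next()
        if tok == "}":
            break
        if tok == "type":
            s.expect("discrete")
            s.expect("[")
            n = int(s.next())
            s.expect("]")
            s.expect("{")
            states = []
            while True:
                t = s.next()
                if t == "}":
                    break
                if t != ",":
                    states.append(t)
            s.expect(";")
            if len(states) != n:
                raise BIFParseError(
                    f"variable {name!r}: declared {n} states, listed {len(states)}",
                    s.line,
                )
        elif tok == "property":
            words = []
            while s.peek() != ";":
                words.append(s.next())
            s.expect(";")
            if len(words) == 2 and words[0] == "tag":
                tag = words[1]
        else:
            raise BIFParseError(f"unexpected token {tok!r} in variable block", s.line)
    if states is None:
        raise BIFParseError(f"variable {name!r} has no type declaration", s.line)
    return Variable(name, tuple(states), tag=tag)


def _parse_probability(s: _Stream):
    line = s.line
    s.expect("(")
    owner = s.next()
    parents = []
    tok = s.next()
    if tok == "|":
        while True:
            parents.append(s.next())
            tok = s.next()
            if tok == ")":
                break
            if tok != ",":
                raise BIFParseError(f"expected ',' in parent list, got {tok!r}", s.line)
    elif tok != ")":
        raise BIFParseError(f"expected ')' after owner, got {tok!r}", s.line)
    s.expect("{")
    rows, table_row = [], None
    while True:
        tok = s.next()
        if tok == "}":
            break
        if tok == "table":
            values = []
            while s.peek() != ";":
                t = s.next()
                if t != ",":
                    values.append(_to_float(t, s.line))
            s.expect(";")
            table_row = values
        elif tok == "(":
            config = []
            while True:
                t = s.next()
                if t == ")":
                    break
                if t != ",":
                    config.append(t)
            rline = s.line
            values = []
            while s.peek() != ";":
                t = s.next()
                if t != ",":
                    values.append(_to_float(t, s.line))
            s.expect(";")
            rows.append((tuple(config), values, rline))
        else:
            raise BIFParseError(
                f"unexpected token {tok!r} in probability block", s.line
            )
    return owner, tuple(parents), rows, table_row, line


def _to_float(tok, line):
    try:
        return float(tok)
    except ValueError:
        raise BIFParseError(f"expected a probability, got {tok!r}", line) from None


# ---------------------------------------------------------------------------
# writing


def _check_token(label, kind):
    if not _WORD.fullmatch(str(label)):
        raise ValueError(f"{kind} {label!r} is not BIF-serializable")
    return str(label)


def write_bif(net: Network, path, name: str = "network"):
    """Serialize a network to BIF 0.15.  Probabilities use 17 significant
    digits, which round-trips IEEE doubles exactly."""
    lines = [f"network {_check_token(name, 'network name')} {{", "}"]
    for v in net.variables:
        lines.append(f"variable {_check_token(v.name, 'variable name')} {{")
        states = ", ".join(_check_token(st, "state label") for st in v.states)
        lines.append(f"  type discrete [ {v.n_states} ] {{ {states} }};")
        if v.tag != "untagged":
            lines.append(f"  property tag {v.tag} ;")
        lines.append("}")
    for v in net.variables:
        c = net.cpts[v.name]
        if c.parents:
            head = f"probability ( {v.name} | {', '.join(c.parents)} ) {{"
            lines.append(head)
            for r, config in enumerate(net.parent_configs(v.name)):
                vals = ", ".join(f"{x:.17g}" for x in c.table[r])
                lines.append(f"  ( {', '.join(map(str, config))} ) {vals};")
            lines.append("}")
        else:
            lines.append(f"probability ( {v.name} ) {{")
            vals = ", ".join(f"{x:.17g}" for x in c.table[0])
            lines.append(f"  table {vals};")
            lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# datasets and tag maps


def read_dataset(path, class_variable: str, missing_marker: str = MISSING) -> RecordDataset:
    """CSV dialect: header row of variable names, cells are state labels,
    missing cells equal to ``missing_marker`` (default: empty)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return RecordDataset(
        frame=frame, class_variable=class_variable, missing_marker=missing_marker
    )


def write_dataset(data: RecordDataset, path):
    data.frame.to_csv(path, index=False)


def read_normals(path) -> dict:
    """Two-column CSV (variable, normal state) -> dict for imputation."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(frame.columns)
    if len(cols) != 2:
        raise ValueError(f"normals file must have exactly 2 columns, found {cols}")
    return dict(zip(frame[cols[0]], frame[cols[1]]))


def write_normals(normals: dict, path):
    pd.DataFrame(
        {"variable": list(normals.keys()), "normal_state": list(normals.values())}
    ).to_csv(path, index=False)


def read_tags(path) -> dict:
    """Two-column CSV (variable, tag) -> dict."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(frame.columns)
    if len(cols) != 2:
        raise ValueError(f"tag file must have exactly 2 columns, found {cols}")
    return dict(zip(frame[cols[0]], frame[cols[1]]))


def write_tags(tags: dict, path):
    pd.DataFrame(
        {"variable": list(tags.keys()), "tag": list(tags.values())}
    ).to_csv(path, index=False)
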