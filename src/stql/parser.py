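"""Tokenizer, recursive-descent parser and canonical pretty-printer.

Keywords are case-insensitive; identifiers are case-sensitive.  String
literals use single quotes.  A submission is either one statement or a
semicolon-separated script.  Syntax errors are rejected with position
and an expected-token hint before anything executes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

from .ast_nodes import (
    AggFunc, AndPred, AttrRef, BinOp, BinsSource, ClosestPred, Comparison,
    ConstIntervalNode, CreateTrack, CreateTrackAs, DistanceFunc, DropTrack,
    ForLoop, LengthFunc, LoadData, LocationComp, NotPred, Num, OrPred,
    OverlapJoinSource, PatternMatch, RawTrack, RegQuery, SelectItem,
    Statement, Str, SubquerySource, TransformSource, TrackSource,
    UnionSource, ValueClause,
)
from .model import StqlError
from .values import VD_OPS

__all__ = ["parse", "parse_script", "canonicalize", "StqlSyntaxError"]


class StqlSyntaxError(StqlError):
    def __init__(self, message: str, line: int, col: int,
                 expected: Optional[list[str]] = None):
        self.line, self.col = line, col
        self.expected = expected or []
        hint = f" (expected {', '.join(self.expected)})" if expected else ""
        super().__init__(f"syntax error at line {line}, column {col}: "
                         f"{message}{hint}")


@dataclass
class Token:
    kind: str  # IDENT NUMBER STRING OP EOF
    text: str
    line: int
    col: int


_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<comment>--[^\n]*)
  | (?P<number>\d+(?:\.\d+)?)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<string>'(?:[^']|'')*')
  | (?P<op><=|>=|!=|[-+*/<>=(),;.\[\]])
    """,
    re.VERBOSE,
)

#: words that terminate an implicit (AS-less) track alias
RESERVED = {
    "select", "from", "where", "group", "order", "by", "and", "or", "not",
    "as", "on", "with", "using", "like", "is", "in", "into", "union",
    "all", "distinct", "coalesce", "discretize", "project", "intersectjoin",
    "exclusivejoin", "generate", "bins", "length", "distance", "create",
    "drop", "track", "load", "data", "local", "inpath", "overwrite", "for",
    "combined", "left", "right", "outer", "join", "precedes", "follows",
    "contains", "overlaps", "coincides", "metadata", "model", "each",
    "total", "count", "sum", "avg", "min", "max",
}

_AGG_FUNCS = {"count", "sum", "avg", "min", "max"}

#: multi-word location relations, longest match first
_LOC_OPS = [
    ("is", "closest", "to", "each"),  # handled separately (predicate)
    ("is", "adjacent", "to"),
    ("is", "prefix", "of"),
    ("is", "suffix", "of"),
    ("is", "upstream", "of"),
    ("is", "downstream", "of"),
    ("is", "within"),
    ("overlaps", "with"),
    ("coincides", "with"),
    ("contains",),
    ("precedes",),
    ("follows",),
]


def tokenize(text: str) -> list[Token]:
    tokens: list[Token] = []
    line, col, pos = 1, 1, 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise StqlSyntaxError(f"unexpected character {text[pos]!r}",
                                  line, col)
        kind = m.lastgroup
        chunk = m.group()
        if kind not in ("ws", "comment"):
            if kind == "number":
                tokens.append(Token("NUMBER", chunk, line, col))
            elif kind == "ident":
                tokens.append(Token("IDENT", chunk, line, col))
            elif kind == "string":
                tokens.append(Token("STRING", chunk[1:-1].replace("''", "'"),
                                    line, col))
            else:
                tokens.append(Token("OP", chunk, line, col))
        nl = chunk.count("\n")
        if nl:
            line += nl
            col = len(chunk) - chunk.rfind("\n")
        else:
            col += len(chunk)
        pos = m.end()
    tokens.append(Token("EOF", "", line, col))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.tokens = tokenize(text)
        self.i = 0

    # -- primitives ---------------------------------------------------
    def peek(self, k: int = 0) -> Token:
        return self.tokens[min(self.i + k, len(self.tokens) - 1)]

    def next(self) -> Token:
        tok = self.tokens[self.i]
        if tok.kind != "EOF":
            self.i += 1
        return tok

    def error(self, message: str, expected: Optional[list[str]] = None):
        tok = self.peek()
        where = f"{tok.kind} {tok.text!r}" if tok.kind != "EOF" else "end of input"
        raise StqlSyntaxError(f"{message}, found {where}",
                              tok.line, tok.col, expected)

    def at_kw(self, *words: str, offset: int = 0) -> bool:
        for k, w in enumerate(words):
            tok = self.peek(offset + k)
            if tok.kind != "IDENT" or tok.text.lower() != w:
                return False
        return True

    def accept_kw(self, *words: str) -> bool:
        if self.at_kw(*words):
            self.i += len(words)
            return True
        return False

    def expect_kw(self, *words: str) -> None:
        if not self.accept_kw(*words):
            self.error(f"expected {' '.join(words).upper()}",
                       [" ".join(words).upper()])

    def accept_op(self, text: str) -> bool:
        tok = self.peek()
        if tok.kind == "OP" and tok.text == text:
            self.i += 1
            return True
        return False

    def expect_op(self, text: str) -> Token:
        tok = self.peek()
        if tok.kind != "OP" or tok.text != text:
            self.error(f"expected {text!r}", [text])
        return self.next()

    def expect_ident(self, what: str = "identifier") -> Token:
        tok = self.peek()
        if tok.kind != "IDENT":
            self.error(f"expected {what}", [what])
        return self.next()

    def pos(self) -> tuple[int, int]:
        tok = self.peek()
        return (tok.line, tok.col)

    # -- statements ---------------------------------------------------
    def parse_script(self) -> list[Statement]:
        stmts = [self.parse_statement()]
        while self.accept_op(";"):
            if self.peek().kind == "EOF":
                break
            stmts.append(self.parse_statement())
        if self.peek().kind != "EOF":
            self.error("trailing input after statement")
        return stmts

    def parse_statement(self) -> Statement:
        if self.at_kw("create"):
            return self.parse_create()
        if self.at_kw("drop"):
            return self.parse_drop()
        if self.at_kw("load"):
            return self.parse_load()
        if self.at_kw("for"):
            return self.parse_for_loop()
        if self.at_kw("select"):
            return self.parse_reg_query()
        self.error("expected a statement",
                   ["SELECT", "CREATE", "DROP", "LOAD", "FOR"])

    def parse_create(self) -> Union[CreateTrack, CreateTrackAs]:
        p = self.pos()
        self.expect_kw("create", "track")
        name = self.expect_ident("track name").text
        if self.accept_kw("as"):
            return CreateTrackAs(name, self.parse_reg_query(), pos=p)
        self.expect_op("(")
        schema = []
        while True:
            attr = self.expect_ident("attribute name").text
            typ_tok = self.expect_ident("data type")
            typ = typ_tok.text.lower()
            if typ not in ("string", "int", "float"):
                raise StqlSyntaxError(
                    f"unknown data type {typ_tok.text!r}",
                    typ_tok.line, typ_tok.col, ["string", "int", "float"])
            schema.append((attr, typ))
            if not self.accept_op(","):
                break
        self.expect_op(")")
        return CreateTrack(name, schema, pos=p)

    def parse_drop(self) -> DropTrack:
        p = self.pos()
        self.expect_kw("drop", "track")
        return DropTrack(self.expect_ident("track name").text, pos=p)

    def parse_load(self) -> LoadData:
        p = self.pos()
        self.expect_kw("load", "data", "local", "inpath")
        tok = self.peek()
        if tok.kind != "STRING":
            self.error("expected a quoted file path", ["'<path>'"])
        path = self.next().text
        overwrite = self.accept_kw("overwrite")
        self.expect_kw("into", "track")
        return LoadData(path, self.expect_ident("track name").text,
                        overwrite=overwrite, pos=p)

    def parse_for_loop(self) -> ForLoop:
        p = self.pos()
        self.expect_kw("for", "track")
        var = self.expect_ident("track variable").text
        self.expect_kw("in")
        self.expect_op("(")
        # category: quoted string or a run of identifiers/numbers
        if self.peek().kind == "STRING":
            category = self.next().text
        else:
            words = [self.expect_ident("track category").text]
            while self.peek().kind in ("IDENT", "NUMBER") and not (
                self.peek(1).kind == "OP" and self.peek(1).text in ("=",)
            ) and not self.at_kw("like", offset=1) \
                    and not self.at_kw("not", "like", offset=1):
                if self.peek().kind == "OP":
                    break
                words.append(self.next().text)
                if self.peek().kind == "OP" and self.peek().text in (",", ")"):
                    break
            category = " ".join(words)
        conditions = []
        if self.accept_op(","):
            while True:
                attr = self.expect_ident("selection attribute").text
                if self.accept_op("="):
                    op = "="
                elif self.accept_kw("not", "like"):
                    op = "NOT LIKE"
                elif self.accept_kw("like"):
                    op = "LIKE"
                else:
                    self.error("expected = or LIKE in track selection",
                               ["=", "LIKE"])
                tok = self.peek()
                if tok.kind != "STRING":
                    self.error("expected a quoted value", ["'<value>'"])
                conditions.append((attr, op, self.next().text))
                if not self.accept_kw("and"):
                    break
        self.expect_op(")")
        if self.at_kw("create"):
            body = self.parse_create()
            if not isinstance(body, CreateTrackAs):
                self.error("FOR TRACK IN body must be a query or CREATE "
                           "TRACK ... AS")
            return ForLoop(var, category, conditions, body,
                           form="per_track", pos=p)
        body = self.parse_reg_query()
        self.expect_kw("combined", "with", "union", "as")
        output = self.expect_ident("output track name").text
        return ForLoop(var, category, conditions, body, output=output,
                       form="union", pos=p)

    # -- SELECT queries -----------------------------------------------
    def parse_reg_query(self) -> RegQuery:
        p = self.pos()
        self.expect_kw("select")
        distinct = self.accept_kw("distinct")
        if self.accept_op("*"):
            items: Union[list, str] = "*"
        else:
            items = [self.parse_select_item()]
            while self.accept_op(","):
                items.append(self.parse_select_item())
        self.expect_kw("from")
        sources = [self.parse_track_source()]
        join_kind = None
        for kind in ("left", "right", "outer"):
            if self.accept_kw(kind, "join"):
                join_kind = kind
                sources.append(self.parse_track_source())
                break
        if join_kind is None:
            while self.accept_op(","):
                sources.append(self.parse_track_source())
        where = None
        if self.accept_kw("where"):
            where = self.parse_where_body()
        groupby, orderby = [], []
        if self.accept_kw("group", "by"):
            groupby = [self.parse_attr_ref()]
            while self.accept_op(","):
                groupby.append(self.parse_attr_ref())
        if self.accept_kw("order", "by"):
            orderby = [self.parse_attr_ref()]
            while self.accept_op(","):
                orderby.append(self.parse_attr_ref())
        return RegQuery(items, sources, distinct=distinct,
                        join_kind=join_kind, where=where,
                        groupby=groupby, orderby=orderby, pos=p)

    def parse_select_item(self) -> SelectItem:
        p = self.pos()
        expr = self.parse_arith()
        alias = None
        if self.accept_kw("as"):
            alias = self.expect_ident("attribute alias").text
        return SelectItem(expr, alias, pos=p)

    # -- FROM sources -------------------------------------------------
    def parse_track_source(self) -> TrackSource:
        src = self.parse_track_base()
        # unparenthesized overlap join: T1 intersectjoin T2 ...
        if self.at_kw("intersectjoin") or self.at_kw("exclusivejoin"):
            op = self.next().text.lower()
            right = self.parse_track_base()
            vc = self.parse_value_clause()
            return OverlapJoinSource(op, src, right, vc, pos=src.pos)
        return src

    def parse_track_base(self) -> TrackSource:
        p = self.pos()
        if self.at_kw("coalesce") or self.at_kw("discretize"):
            op = self.next().text.lower()
            track = self.parse_track_base()
            vc = self.parse_value_clause(allow_metadata=False)
            return TransformSource(op, track, vc, pos=p)
        if self.accept_kw("project"):
            left = self.parse_track_base()
            self.expect_kw("on")
            if self.at_kw("generate"):
                right: Union[TrackSource, BinsSource] = self.parse_bins()
            else:
                right = self.parse_track_base()
            vc = self.parse_value_clause()
            return OverlapJoinSource("project", left, right, vc, pos=p)
        if self.accept_op("("):
            return self.parse_parenthesized(p)
        return self.parse_raw_track(p)

    def parse_bins(self) -> BinsSource:
        p = self.pos()
        self.expect_kw("generate", "bins", "with", "length")
        tok = self.peek()
        if tok.kind != "NUMBER" or "." in tok.text:
            self.error("expected an integer bin size", ["<integer>"])
        return BinsSource(int(self.next().text), pos=p)

    def parse_parenthesized(self, p) -> TrackSource:
        if self.at_kw("select"):
            query = self.parse_reg_query()
            self.expect_op(")")
            alias = self.parse_alias(required=True)
            return SubquerySource(query, alias, pos=p)
        inner = self.parse_track_base()
        if self.at_kw("union"):
            tracks = [inner]
            while self.accept_kw("union", "all"):
                tracks.append(self.parse_track_base())
            self.expect_op(")")
            alias = self.parse_alias(required=True)
            return UnionSource(tracks, alias, pos=p)
        if self.at_kw("intersectjoin") or self.at_kw("exclusivejoin"):
            op = self.next().text.lower()
            right = self.parse_track_base()
            vc = self.parse_value_clause()
            self.expect_op(")")
            alias = self.parse_alias(required=True)
            return OverlapJoinSource(op, inner, right, vc, alias=alias, pos=p)
        self.expect_op(")")
        alias = self.parse_alias(required=False)
        if isinstance(inner, (TransformSource, OverlapJoinSource)) \
                and inner.alias is None:
            inner.alias = alias
            return inner
        if alias is None:
            return inner
        self.error("unexpected alias after parenthesized track")

    def parse_raw_track(self, p) -> RawTrack:
        if self.peek().kind == "IDENT" \
                and self.peek().text.lower() in RESERVED:
            self.error("expected a track name", ["<track name>"])
        first = self.expect_ident("track name")
        category = None
        name = first.text
        if self.accept_op("."):
            category = first.text
            name = self.expect_ident("track name").text
        as_kw = False
        alias = None
        if self.accept_kw("as"):
            as_kw = True
            alias = self.expect_ident("track alias").text
        elif (self.peek().kind == "IDENT"
              and self.peek().text.lower() not in RESERVED):
            alias = self.next().text
        return RawTrack(name, category=category, alias=alias,
                        as_kw=as_kw, pos=p)

    def parse_alias(self, required: bool) -> Optional[str]:
        self.accept_kw("as")
        tok = self.peek()
        if tok.kind == "IDENT" and tok.text.lower() not in RESERVED:
            return self.next().text
        if required:
            self.error("expected a track alias", ["<alias>"])
        return None

    def parse_value_clause(self, allow_metadata: bool = True) -> ValueClause:
        vc = ValueClause()
        if not self.accept_kw("with"):
            return vc
        parts = 0
        while True:
            if allow_metadata and self.accept_kw("metadata"):
                vc.metadata = True
            else:
                tok = self.peek()
                if tok.kind != "IDENT" or tok.text.lower() not in VD_OPS:
                    self.error("expected a vd_* operator or metadata",
                               sorted(VD_OPS))
                vc.vd = self.next().text.lower()
                self.expect_kw("using")
                mtok = self.expect_ident("value model")
                model = mtok.text.lower()
                if model not in ("each", "all", "total"):
                    raise StqlSyntaxError(
                        f"unknown value model {mtok.text!r}",
                        mtok.line, mtok.col, ["each", "all", "total"])
                vc.model = "each" if model == "each" else "total"
                self.expect_kw("model")
            parts += 1
            if parts < 2 and allow_metadata and self.accept_op(","):
                continue
            break
        return vc

    # -- expressions --------------------------------------------------
    def parse_attr_ref(self) -> AttrRef:
        p = self.pos()
        first = self.expect_ident("attribute name").text
        if self.accept_op("."):
            return AttrRef(first, self.expect_ident("attribute name").text,
                           pos=p)
        return AttrRef(None, first, pos=p)

    def parse_arith(self):
        p = self.pos()
        node = self.parse_term()
        while self.peek().kind == "OP" and self.peek().text in ("+", "-"):
            op = self.next().text
            node = BinOp(op, node, self.parse_term(), pos=p)
        return node

    def parse_term(self):
        p = self.pos()
        node = self.parse_elem()
        while self.peek().kind == "OP" and self.peek().text in ("*", "/"):
            op = self.next().text
            node = BinOp(op, node, self.parse_elem(), pos=p)
        return node

    def parse_elem(self):
        p = self.pos()
        tok = self.peek()
        if tok.kind == "NUMBER":
            self.next()
            return Num(float(tok.text), pos=p)
        if tok.kind == "STRING":
            self.next()
            return Str(tok.text, pos=p)
        if tok.kind == "OP" and tok.text == "-":
            self.next()
            inner = self.parse_elem()
            if isinstance(inner, Num):
                return Num(-inner.value, pos=p)
            return BinOp("-", Num(0.0, pos=p), inner, pos=p)
        if tok.kind == "OP" and tok.text == "(":
            self.next()
            node = self.parse_arith()
            self.expect_op(")")
            return node
        if self.at_kw("length") and self.peek(1).text == "(":
            self.next()
            self.expect_op("(")
            target = self.parse_track_or_const()
            self.expect_op(")")
            return LengthFunc(target, pos=p)
        if self.at_kw("distance") and self.peek(1).text == "(":
            self.next()
            self.expect_op("(")
            left = self.parse_track_or_const()
            self.expect_op(",")
            right = self.parse_track_or_const()
            self.expect_op(")")
            return DistanceFunc(left, right, pos=p)
        if tok.kind == "IDENT" and tok.text.lower() in _AGG_FUNCS \
                and self.peek(1).text == "(":
            fn = self.next().text.lower()
            self.expect_op("(")
            if self.accept_op("*"):
                arg = None
            else:
                arg = self.parse_attr_ref()
            self.expect_op(")")
            return AggFunc(fn, arg, pos=p)
        if tok.kind == "IDENT":
            return self.parse_attr_ref()
        self.error("expected an expression",
                   ["<number>", "<attribute>", "length(", "distance(", "("])

    def parse_const_interval(self) -> ConstIntervalNode:
        p = self.pos()
        self.expect_op("[")
        chrom = self.expect_ident("chromosome").text
        self.expect_op(",")
        start = int(self.expect_number("chrstart"))
        self.expect_op(",")
        end = int(self.expect_number("chrend"))
        strand = None
        if self.accept_op(","):
            tok = self.peek()
            if tok.kind == "OP" and tok.text in ("+", "-"):
                strand = self.next().text
            else:
                self.error("expected + or - strand", ["+", "-"])
        self.expect_op("]")
        return ConstIntervalNode(chrom, start, end, strand, pos=p)

    def expect_number(self, what: str) -> float:
        tok = self.peek()
        if tok.kind != "NUMBER":
            self.error(f"expected {what}", ["<number>"])
        return float(self.next().text)

    def parse_track_or_const(self):
        if self.peek().kind == "OP" and self.peek().text == "[":
            return self.parse_const_interval()
        return self.expect_ident("track name").text

    # -- predicates ---------------------------------------------------
    def parse_where_body(self):
        # closest predicate: TRACK is closest to each TRACK
        if self.peek().kind == "IDENT" \
                and self.at_kw("is", "closest", "to", "each", offset=1):
            p = self.pos()
            left = self.next().text
            self.expect_kw("is", "closest", "to", "each")
            right = self.expect_ident("track name").text
            return ClosestPred(left, right, pos=p)
        return self.parse_or_pred()

    def parse_or_pred(self):
        p = self.pos()
        node = self.parse_and_pred()
        operands = [node]
        while self.accept_kw("or"):
            operands.append(self.parse_and_pred())
        return operands[0] if len(operands) == 1 else OrPred(operands, pos=p)

    def parse_and_pred(self):
        p = self.pos()
        operands = [self.parse_not_pred()]
        while self.accept_kw("and"):
            operands.append(self.parse_not_pred())
        return operands[0] if len(operands) == 1 else AndPred(operands, pos=p)

    def parse_not_pred(self):
        p = self.pos()
        if self.accept_kw("not"):
            return NotPred(self.parse_not_pred(), pos=p)
        if self.peek().kind == "OP" and self.peek().text == "(" \
                and self._paren_is_predicate():
            self.next()
            node = self.parse_or_pred()
            self.expect_op(")")
            return node
        return self.parse_predicate()

    def _paren_is_predicate(self) -> bool:
        """Distinguish '(chrstart + 1) > x' from '(a = b or c = d)'."""
        depth = 0
        k = 0
        while True:
            tok = self.peek(k)
            if tok.kind == "EOF":
                return False
            if tok.kind == "OP":
                if tok.text == "(":
                    depth += 1
                elif tok.text == ")":
                    depth -= 1
                    if depth == 0:
                        return False  # closed without predicate content
                elif depth == 1 and tok.text in ("<", ">", "=", "!=",
                                                 "<=", ">="):
                    return True
            if tok.kind == "IDENT" and depth >= 1 and tok.text.lower() in (
                "and", "or", "not", "like", "is", "overlaps", "coincides",
                "precedes", "follows",
            ):
                return True
            k += 1

    def parse_predicate(self):
        p = self.pos()
        # constant interval on the left forces a location comparison
        if self.peek().kind == "OP" and self.peek().text == "[":
            left = self.parse_const_interval()
            rel = self.parse_loc_op(required=True)
            right = self.parse_loc_operand()
            return LocationComp(left, rel, right, pos=p)
        # bare track name followed by a relation keyword
        if self.peek().kind == "IDENT":
            save = self.i
            name = self.next().text
            rel = self.parse_loc_op(required=False)
            if rel is not None:
                right = self.parse_loc_operand()
                return LocationComp(name, rel, right, pos=p)
            self.i = save
        expr = self.parse_arith()
        if isinstance(expr, AttrRef):
            if self.accept_kw("not", "like"):
                return self._pattern(expr, True, p)
            if self.accept_kw("like"):
                return self._pattern(expr, False, p)
        tok = self.peek()
        if tok.kind == "OP" and tok.text in ("<", ">", "=", "!=", "<=", ">="):
            op = self.next().text
            right = self.parse_arith()
            return Comparison(op, expr, right, pos=p)
        self.error("expected a comparison operator or LIKE",
                   ["<", ">", "=", "!=", "<=", ">=", "LIKE"])

    def _pattern(self, attr: AttrRef, negated: bool, p) -> PatternMatch:
        tok = self.peek()
        if tok.kind != "STRING":
            self.error("expected a quoted pattern", ["'<pattern>'"])
        return PatternMatch(attr, self.next().text, negated=negated, pos=p)

    def parse_loc_op(self, required: bool) -> Optional[str]:
        for words in _LOC_OPS:
            if words == ("is", "closest", "to", "each"):
                continue
            if self.at_kw(*words):
                self.i += len(words)
                return " ".join(words).replace(
                    "is adjacent to", "is adjacent to")
        if required:
            self.error("expected an interval relation",
                       [" ".join(w) for w in _LOC_OPS])
        return None

    def parse_loc_operand(self):
        if self.peek().kind == "OP" and self.peek().text == "[":
            return self.parse_const_interval()
        return self.expect_ident("track name").text


def parse(text: str) -> Statement:
    """Parse a single STQL statement."""
    stmts = parse_script(text)
    if len(stmts) != 1:
        raise StqlSyntaxError("expected a single statement", 1, 1)
    return stmts[0]


def parse_script(text: str) -> list[Statement]:
    """Parse a semicolon-separated script of STQL statements."""
    return _Parser(text).parse_script()


# --------------------------------------------------------------------
# canonical pretty-printer


def _c_expr(e) -> str:
    if isinstance(e, Num):
        v = e.value
        return str(int(v)) if float(v).is_integer() else str(v)
    if isinstance(e, Str):
        return "'" + e.value.replace("'", "''") + "'"
    if isinstance(e, AttrRef):
        return f"{e.track}.{e.attr}" if e.track else e.attr
    if isinstance(e, BinOp):
        left = _c_expr(e.left)
        right = _c_expr(e.right)
        if isinstance(e.left, BinOp) and e.op in ("*", "/") \
                and e.left.op in ("+", "-"):
            left = f"({left})"
        if isinstance(e.right, BinOp) and (
            e.op in ("*", "/") or (e.op == "-" and e.right.op in ("+", "-"))
        ):
            right = f"({right})"
        return f"{left} {e.op} {right}"
    if isinstance(e, LengthFunc):
        return f"LENGTH({_c_locop(e.target)})"
    if isinstance(e, DistanceFunc):
        return f"DISTANCE({_c_locop(e.left)}, {_c_locop(e.right)})"
    if isinstance(e, AggFunc):
        arg = "*" if e.arg is None else _c_expr(e.arg)
        return f"{e.fn.upper()}({arg})"
    raise TypeError(f"unknown expression {e!r}")


def _c_locop(x) -> str:
    if isinstance(x, ConstIntervalNode):
        inner = f"{x.chr}, {x.chrstart}, {x.chrend}"
        if x.strand:
            inner += f", {x.strand}"
        return f"[{inner}]"
    return x


def _c_pred(pr, parent: str = "or") -> str:
    if isinstance(pr, OrPred):
        s = " OR ".join(_c_pred(o, "or") for o in pr.operands)
        return f"({s})" if parent != "or" else s
    if isinstance(pr, AndPred):
        s = " AND ".join(_c_pred(o, "and") for o in pr.operands)
        return f"({s})" if parent == "not" else s
    if isinstance(pr, NotPred):
        inner = _c_pred(pr.operand, "not")
        return f"NOT {inner}"
    if isinstance(pr, Comparison):
        return f"{_c_expr(pr.left)} {pr.op} {_c_expr(pr.right)}"
    if isinstance(pr, LocationComp):
        rel = pr.rel.upper()
        return f"{_c_locop(pr.left)} {rel} {_c_locop(pr.right)}"
    if isinstance(pr, PatternMatch):
        neg = "NOT " if pr.negated else ""
        pat = pr.pattern.replace("'", "''")
        return f"{_c_expr(pr.attr)} {neg}LIKE '{pat}'"
    if isinstance(pr, ClosestPred):
        return f"{pr.left} IS CLOSEST TO EACH {pr.right}"
    raise TypeError(f"unknown predicate {pr!r}")


def _c_value_clause(vc: ValueClause) -> str:
    parts = []
    if vc.vd:
        model = "EACH" if vc.model in (None, "each") else "TOTAL"
        parts.append(f"{vc.vd} USING {model} MODEL")
    if vc.metadata:
        parts.append("METADATA")
    return f" WITH {', '.join(parts)}" if parts else ""


def _c_source(src) -> str:
    if isinstance(src, RawTrack):
        out = f"{src.category}.{src.name}" if src.category else src.name
        if src.alias:
            out += f" AS {src.alias}" if src.as_kw else f" {src.alias}"
        return out
    if isinstance(src, BinsSource):
        return f"GENERATE BINS WITH LENGTH {src.bin_size}"
    if isinstance(src, TransformSource):
        body = f"{src.op.upper()} {_c_source(src.track)}" \
               + _c_value_clause(src.value_clause)
        if src.alias:
            return f"({body}) {src.alias}"
        return body
    if isinstance(src, OverlapJoinSource):
        if src.op == "project":
            body = (f"PROJECT {_c_source(src.left)} ON "
                    f"{_c_source(src.right)}")
        else:
            body = (f"{_c_source(src.left)} {src.op.upper()} "
                    f"{_c_source(src.right)}")
        body += _c_value_clause(src.value_clause)
        if src.alias:
            return f"({body}) {src.alias}"
        return body
    if isinstance(src, SubquerySource):
        return f"({canonicalize(src.query)}) {src.alias}"
    if isinstance(src, UnionSource):
        inner = " UNION ALL ".join(_c_source(t) for t in src.tracks)
        return f"({inner}) {src.alias}"
    raise TypeError(f"unknown source {src!r}")


def canonicalize(stmt) -> str:
    """Deterministic pretty-printed STQL; re-parsing yields an equal AST."""
    if isinstance(stmt, RegQuery):
        items = "*" if stmt.items == "*" else ", ".join(
            _c_expr(it.expr) + (f" AS {it.alias}" if it.alias else "")
            for it in stmt.items
        )
        head = "SELECT DISTINCT" if stmt.distinct else "SELECT"
        if stmt.join_kind:
            src = (f"{_c_source(stmt.sources[0])} {stmt.join_kind.upper()} "
                   f"JOIN {_c_source(stmt.sources[1])}")
        else:
            src = ", ".join(_c_source(s) for s in stmt.sources)
        out = f"{head} {items} FROM {src}"
        if stmt.where is not None:
            out += f" WHERE {_c_pred(stmt.where)}"
        if stmt.groupby:
            out += " GROUP BY " + ", ".join(_c_expr(a) for a in stmt.groupby)
        if stmt.orderby:
            out += " ORDER BY " + ", ".join(_c_expr(a) for a in stmt.orderby)
        return out
    if isinstance(stmt, CreateTrack):
        schema = ", ".join(f"{n} {t}" for n, t in stmt.schema)
        return f"CREATE TRACK {stmt.name} ({schema})"
    if isinstance(stmt, CreateTrackAs):
        return f"CREATE TRACK {stmt.name} AS {canonicalize(stmt.query)}"
    if isinstance(stmt, DropTrack):
        return f"DROP TRACK {stmt.name}"
    if isinstance(stmt, LoadData):
        ow = " OVERWRITE" if stmt.overwrite else ""
        path = stmt.path.replace("'", "''")
        return f"LOAD DATA LOCAL INPATH '{path}'{ow} INTO TRACK {stmt.track}"
    if isinstance(stmt, ForLoop):
        conds = "".join(
            f" AND {a} {op} '{v}'" if k else f", {a} {op} '{v}'"
            for k, (a, op, v) in enumerate(stmt.conditions)
        )
        head = f"FOR TRACK {stmt.var} IN ({stmt.category}{conds}) "
        if stmt.form == "union":
            return (head + canonicalize(stmt.body)
                    + f" COMBINED WITH UNION AS {stmt.output}")
        return head + canonicalize(stmt.body)
    raise TypeError(f"unknown statement {stmt!r}")


def canonicalize_script(stmts: list[Statement]) -> str:
    return ";\n".join(canonicalize(s) for s in stmts)
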