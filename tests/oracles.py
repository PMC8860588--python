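"""Independent brute-force oracles for the test suite.

The scanning oracle is a recursive-descent matcher that enumerates block
and loop placements explicitly, exploring them in leftmost-greedy
(backtracking-engine) preference order. It shares no pattern-compilation
machinery with the package's regex-based scanner; agreement between the
two is therefore a meaningful check of the scanner's semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

LOOP_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class Run:
    base: str
    min_len: int
    exact: bool = False


@dataclass(frozen=True)
class Loop:
    min_len: int
    max_len: int


def elements_for_class(class_id: str, composition: str = "AAAA"):
    """Pattern element list for the fixed-block classes (G on plus strand)."""
    if class_id == "canonical":
        runs, loop = [Run("G", 3)] * 4, Loop(1, 7)
    elif class_id == "extended":
        runs, loop = [Run("G", 3)] * 4, Loop(1, 12)
    elif class_id == "interstrand":
        runs = [Run("G" if c == "A" else "C", 3) for c in composition]
        loop = Loop(1, 7)
    else:
        raise ValueError(class_id)
    elems: list = []
    for i, run in enumerate(runs):
        if i:
            elems.append(loop)
        elems.append(run)
    return elems


def _max_run(seq: str, pos: int, base: str) -> int:
    n = 0
    while pos + n < len(seq) and seq[pos + n] == base:
        n += 1
    return n


def _max_loop(seq: str, pos: int, cap: int) -> int:
    n = 0
    while n < cap and pos + n < len(seq) and seq[pos + n] in LOOP_ALPHABET:
        n += 1
    return n


def greedy_match_fixed(seq: str, elems, pos: int, memo=None) -> int | None:
    """End of the leftmost-greedy match of a fixed element list at pos.

    Explores run lengths and loop lengths longest-first with full
    backtracking, i.e. the preference order of a greedy regex engine.
    """
    if memo is None:
        memo = {}

    def match(idx: int, p: int):
        key = (idx, p)
        if key in memo:
            return memo[key]
        if idx == len(elems):
            memo[key] = p
            return p
        elem = elems[idx]
        result = None
        if isinstance(elem, Run):
            avail = _max_run(seq, p, elem.base)
            if avail >= elem.min_len:
                lengths = (
                    [elem.min_len]
                    if elem.exact
                    else range(avail, elem.min_len - 1, -1)
                )
                for length in lengths:
                    result = match(idx + 1, p + length)
                    if result is not None:
                        break
        else:
            avail = _max_loop(seq, p, elem.max_len)
            for length in range(avail, elem.min_len - 1, -1):
                result = match(idx + 1, p + length)
                if result is not None:
                    break
        memo[key] = result
        return result

    return match(0, pos)


def greedy_match_two_tetrad(seq: str, pos: int, memo=None) -> int | None:
    """Greedy match end of (G{2} loop{1,12}){3,} G{2} at pos.

    The repetition prefers one more unit over stopping; within a unit the
    loop is greedy. Failure states are memoized on (position, capped unit
    count) — the match end from a position is identical for every count
    >= 3, so the cap keeps the search polynomial.
    """
    if memo is None:
        memo = {}

    def tail(p: int) -> int | None:
        return p + 2 if seq[p : p + 2] == "GG" else None

    def rep(p: int, count: int):
        key = (p, min(count, 3))
        if key in memo:
            return memo[key]
        result = None
        if seq[p : p + 2] == "GG":
            after = p + 2
            avail = _max_loop(seq, after, 12)
            for length in range(avail, 0, -1):
                result = rep(after + length, count + 1)
                if result is not None:
                    break
        if result is None and count >= 3:
            result = tail(p)
        memo[key] = result
        return result

    return rep(pos, 0)


def oracle_scan(seq: str, class_id: str, composition: str = "AAAA"):
    """Non-overlapping leftmost-greedy scan, oracle implementation.

    Returns sorted (start, end) spans on the given sequence as written
    (the caller handles strand orientation conventions).
    """
    spans = []
    pos = 0
    n = len(seq)
    if class_id == "two_tetrad":
        memo: dict = {}
        while pos < n:
            end = greedy_match_two_tetrad(seq, pos, memo)
            if end is not None:
                spans.append((pos, end))
                pos = end
                memo = {}
            else:
                pos += 1
    else:
        elems = elements_for_class(class_id, composition)
        memo = {}
        while pos < n:
            end = greedy_match_fixed(seq, elems, pos, memo)
            if end is not None:
                spans.append((pos, end))
                pos = end
                memo = {}
            else:
                pos += 1
    return spans
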