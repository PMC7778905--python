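"""Reaction equations in the unified namespace.

Equations keep exact rational stoichiometry (`fractions.Fraction`) so that
canonical keys — the reaction deduplication criterion — are bit-stable.
Side membership is positional (left/right lists); coefficients are always
positive.

The balancing machinery distinguishes a *proton-only* imbalance (H and
charge off by the same amount), which is repaired by adding the balancing
proton ``MNXM1``, from genuine mass imbalance, which is only reported.
Protons that cross a compartment boundary (proton motive force) are
relabelled ``MNXM01`` so that transport semantics survive proton balancing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction

__all__ = [
    "Direction",
    "Term",
    "Equation",
    "BalanceVerdict",
    "BalanceReport",
    "UnifiedReaction",
    "PROTON_BALANCE",
    "PROTON_TRANSPORT",
    "parse_equation",
    "format_equation",
    "rewrite_equation",
    "parse_formula",
    "balance_check",
    "proton_balance",
    "classify_transported_protons",
    "canonical_key",
    "build_reaction_namespace",
    "EMPTY_KEY",
]

PROTON_BALANCE = "MNXM1"    # proton added to balance a chemical equation
PROTON_TRANSPORT = "MNXM01"  # transported proton (proton motive force)
EMPTY_KEY = "EMPTY"


class Direction(Enum):
    LR = "LR"
    RL = "RL"
    BIDIRECTIONAL = "B"


@dataclass(frozen=True)
class Term:
    met: str
    coeff: Fraction
    compartment: str | None = None

    def __post_init__(self) -> None:
        if self.coeff <= 0:
            raise ValueError(f"term coefficient must be positive: {self}")


@dataclass(frozen=True)
class Equation:
    left: tuple[Term, ...]
    right: tuple[Term, ...]
    direction: Direction = Direction.LR

    @property
    def is_empty(self) -> bool:
        return not self.left and not self.right


def _combine(terms) -> tuple[Term, ...]:
    acc: dict[tuple[str, str | None], Fraction] = {}
    for t in terms:
        key = (t.met, t.compartment)
        acc[key] = acc.get(key, Fraction(0)) + t.coeff
    return tuple(
        Term(met, coeff, comp)
        for (met, comp), coeff in sorted(acc.items(), key=lambda kv: (kv[0][0], kv[0][1] or ""))
        if coeff != 0
    )


def normalize_equation(eq: Equation) -> Equation:
    """Combine duplicate (metabolite, compartment) terms within each side."""
    return Equation(_combine(eq.left), _combine(eq.right), eq.direction)


# --------------------------------------------------------------------------
# equation text grammar: "2 A@c + B = C", arrows "-->", "<--", "=" (bidir)
# --------------------------------------------------------------------------

_ARROWS = ((" --> ", Direction.LR), (" <-- ", Direction.RL), (" = ", Direction.BIDIRECTIONAL))
_TERM_RE = re.compile(r"^(?:(\d+(?:/\d+)?|\d*\.\d+)\s+)?(\S+?)(?:@(\S+))?$")


def parse_equation(text: str) -> Equation:
    """Parse the shared equation grammar used by source TSVs and flat files."""
    for arrow, direction in _ARROWS:
        if arrow in text:
            lhs, rhs = text.split(arrow, 1)
            break
    else:
        # single-sided equations like "A -->" or "--> A"
        stripped = text.strip()
        if stripped.endswith("-->"):
            lhs, rhs, direction = stripped[:-3], "", Direction.LR
        elif stripped.startswith("-->"):
            lhs, rhs, direction = "", stripped[3:], Direction.LR
        elif stripped.endswith("="):
            lhs, rhs, direction = stripped[:-1], "", Direction.BIDIRECTIONAL
        elif stripped.startswith("="):
            lhs, rhs, direction = "", stripped[1:], Direction.BIDIRECTIONAL
        else:
            raise ValueError(f"no arrow ('-->', '<--' or '=') in equation: {text!r}")
    return Equation(_parse_side(lhs), _parse_side(rhs), direction)


def _parse_side(text: str) -> tuple[Term, ...]:
    text = text.strip()
    if not text:
        return ()
    terms = []
    for chunk in text.split(" + "):
        m = _TERM_RE.match(chunk.strip())
        if not m:
            raise ValueError(f"cannot parse equation term {chunk!r}")
        coeff_s, met, comp = m.groups()
        coeff = Fraction(coeff_s) if coeff_s else Fraction(1)
        terms.append(Term(met, coeff, comp))
    return tuple(terms)


def _format_term(t: Term) -> str:
    met = t.met if t.compartment is None else f"{t.met}@{t.compartment}"
    return met if t.coeff == 1 else f"{t.coeff} {met}"


def format_equation(eq: Equation) -> str:
    lhs = " + ".join(_format_term(t) for t in eq.left)
    rhs = " + ".join(_format_term(t) for t in eq.right)
    arrow = {Direction.LR: "-->", Direction.RL: "<--", Direction.BIDIRECTIONAL: "="}[eq.direction]
    return f"{lhs} {arrow} {rhs}".strip()


# --------------------------------------------------------------------------
# rewriting and balancing
# --------------------------------------------------------------------------

def rewrite_equation(eq: Equation, mapping: dict[str, str]) -> Equation:
    """Substitute metabolite ids, combine like terms and cancel across sides.

    Cancellation removes min(coeff) of every (metabolite, compartment) pair
    present on both sides; an equation whose sides cancel entirely becomes
    empty (and will disappear from any mapped model).
    """
    missing = sorted(
        {t.met for t in (*eq.left, *eq.right) if t.met not in mapping}
    )
    if missing:
        raise KeyError(f"unmapped metabolites in equation: {', '.join(missing)}")
    left = _combine(replace(t, met=mapping[t.met]) for t in eq.left)
    right = _combine(replace(t, met=mapping[t.met]) for t in eq.right)

    lmap = {(t.met, t.compartment): t.coeff for t in left}
    rmap = {(t.met, t.compartment): t.coeff for t in right}
    for key in set(lmap) & set(rmap):
        cancel = min(lmap[key], rmap[key])
        lmap[key] -= cancel
        rmap[key] -= cancel
    mk = lambda m: tuple(
        Term(met, c, comp) for (met, comp), c in sorted(m.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")) if c
    )
    return Equation(mk(lmap), mk(rmap), eq.direction)


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill formula ('.'-separated components allowed) into counts."""
    counts: dict[str, int] = {}
    for comp in formula.split("."):
        mult = 1
        m = re.match(r"^(\d+)([A-Z].*)$", comp)
        if m:
            mult, comp = int(m.group(1)), m.group(2)
        pos = 0
        for m in _FORMULA_RE.finditer(comp):
            if m.start() != pos:
                raise ValueError(f"unparseable formula {formula!r} at {comp[pos:]!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + mult * int(m.group(2) or 1)
        if pos != len(comp):
            raise ValueError(f"unparseable formula {formula!r} at {comp[pos:]!r}")
    return counts


class BalanceVerdict(Enum):
    BALANCED = "BALANCED"
    PROTON_ONLY = "PROTON_ONLY"
    UNBALANCED = "UNBALANCED"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class BalanceReport:
    element_delta: dict[str, Fraction] = field(default_factory=dict)
    charge_delta: Fraction = Fraction(0)
    verdict: BalanceVerdict = BalanceVerdict.UNKNOWN


def balance_check(eq: Equation, structures: dict[str, tuple[str | None, int | None]]) -> BalanceReport:
    """Element and charge deltas (right minus left), coefficient-weighted.

    ``structures`` maps metabolite id to (Hill formula, formal charge); a
    participant missing from the map, or with either field absent, makes the
    verdict UNKNOWN.
    """
    delta: dict[str, Fraction] = {}
    charge = Fraction(0)
    unknown = False
    for sign, side in ((-1, eq.left), (+1, eq.right)):
        for t in side:
            formula, q = structures.get(t.met, (None, None))
            if formula is None or q is None:
                unknown = True
                continue
            for el, n in parse_formula(formula).items():
                delta[el] = delta.get(el, Fraction(0)) + sign * t.coeff * n
            charge += sign * t.coeff * q
    delta = {el: d for el, d in delta.items() if d != 0}
    if unknown:
        verdict = BalanceVerdict.UNKNOWN
    elif not delta and charge == 0:
        verdict = BalanceVerdict.BALANCED
    elif set(delta) == {"H"} and charge == delta["H"]:
        verdict = BalanceVerdict.PROTON_ONLY
    else:
        verdict = BalanceVerdict.UNBALANCED
    return BalanceReport(element_delta=delta, charge_delta=charge, verdict=verdict)


def _majority_compartment(eq: Equation) -> str | None:
    votes: dict[str | None, int] = {}
    for t in (*eq.left, *eq.right):
        votes[t.compartment] = votes.get(t.compartment, 0) + 1
    if not votes:
        return None
    return max(sorted(votes, key=lambda c: c or ""), key=lambda c: votes[c])


def proton_balance(eq: Equation, report: BalanceReport) -> Equation:
    """Repair a proton-only imbalance by adding MNXM1 to the deficient side.

    Refuses to touch BALANCED, UNBALANCED or UNKNOWN equations: a non-proton
    imbalance must never be silently "fixed".
    """
    if report.verdict is not BalanceVerdict.PROTON_ONLY:
        raise ValueError(f"proton_balance requires a PROTON_ONLY report, got {report.verdict.name}")
    n = report.element_delta["H"]
    comp = _majority_compartment(eq)
    proton = Term(PROTON_BALANCE, abs(n), comp)
    if n > 0:  # right side has surplus H: left is deficient
        return normalize_equation(Equation(eq.left + (proton,), eq.right, eq.direction))
    return normalize_equation(Equation(eq.left, eq.right + (proton,), eq.direction))


def classify_transported_protons(eq: Equation) -> Equation:
    """Relabel cross-compartment proton pairs MNXM1 → MNXM01.

    For every pair of compartments (c1 on the left, c2 on the right, c1 ≠ c2)
    the matched amount k = min(left coeff in c1, right coeff in c2) of
    protons is relabelled on both sides; any remainder stays MNXM1.
    Compartment pairs are processed in sorted order for determinism.
    """
    left_h = {
        t.compartment: t.coeff for t in eq.left if t.met == PROTON_BALANCE
    }
    right_h = {
        t.compartment: t.coeff for t in eq.right if t.met == PROTON_BALANCE
    }
    moved_left: dict[str | None, Fraction] = {}
    moved_right: dict[str | None, Fraction] = {}
    for c1 in sorted(left_h, key=lambda c: c or ""):
        for c2 in sorted(right_h, key=lambda c: c or ""):
            if c1 == c2:
                continue
            k = min(left_h[c1], right_h[c2])
            if k <= 0:
                continue
            left_h[c1] -= k
            right_h[c2] -= k
            moved_left[c1] = moved_left.get(c1, Fraction(0)) + k
            moved_right[c2] = moved_right.get(c2, Fraction(0)) + k

    if not moved_left:
        return eq

    def rebuild(side, moved):
        out = []
        for t in side:
            if t.met == PROTON_BALANCE and moved.get(t.compartment):
                k = moved[t.compartment]
                if t.coeff > k:
                    out.append(replace(t, coeff=t.coeff - k))
                out.append(Term(PROTON_TRANSPORT, k, t.compartment))
            else:
                out.append(t)
        return tuple(out)

    return normalize_equation(
        Equation(rebuild(eq.left, moved_left), rebuild(eq.right, moved_right), eq.direction)
    )


# --------------------------------------------------------------------------
# canonicalization and the unified reaction namespace
# --------------------------------------------------------------------------

def _scaled_terms(eq: Equation) -> tuple[tuple[Term, ...], tuple[Term, ...]]:
    coeffs = [t.coeff for t in (*eq.left, *eq.right)]
    if not coeffs:
        return (), ()
    lcm = math.lcm(*(c.denominator for c in coeffs))
    ints = [c.numerator * (lcm // c.denominator) for c in coeffs]
    g = math.gcd(*ints)
    scale = Fraction(lcm, g)
    mk = lambda side: tuple(replace(t, coeff=t.coeff * scale) for t in side)
    return mk(eq.left), mk(eq.right)


def _side_string(terms: tuple[Term, ...]) -> str:
    return " + ".join(
        _format_term(t) for t in sorted(terms, key=lambda t: (t.met, t.compartment or ""))
    )


def canonical_key(eq: Equation) -> tuple[str, bool]:
    """Canonical text key of an equation, plus whether the sides were swapped.

    Coefficients are rescaled to the smallest coprime integers, terms are
    sorted within each side, and the lexicographically smaller side string
    is placed left.  Equal keys ⇔ same reaction up to direction and scaling.
    The returned flag reports whether the orientation was flipped, so the
    caller can fold the direction accordingly.
    """
    eq = normalize_equation(eq)
    if eq.is_empty:
        return EMPTY_KEY, False
    left, right = _scaled_terms(eq)
    ls, rs = _side_string(left), _side_string(right)
    if rs < ls:
        return f"{rs} = {ls}", True
    return f"{ls} = {rs}", False


def _fold_direction(direction: Direction, flipped: bool) -> Direction:
    if not flipped or direction is Direction.BIDIRECTIONAL:
        return direction
    return Direction.RL if direction is Direction.LR else Direction.LR


def merge_directions(directions) -> Direction:
    """Direction of a merged reaction: unanimity or BIDIRECTIONAL."""
    ds = set(directions)
    if len(ds) == 1:
        return ds.pop()
    return Direction.BIDIRECTIONAL


@dataclass
class UnifiedReaction:
    mnx_id: str
    equation: Equation
    key: str
    members: tuple[tuple[str, str], ...]
    reference: tuple[str, str]
    empty: bool
    balance: BalanceReport


def _zero_free_ids(prefix: str, n: int, reserved: frozenset[str]) -> list[str]:
    """Deterministic id sequence: integers whose decimal form has no '0'."""
    out: list[str] = []
    k = 1
    while len(out) < n:
        k += 1
        if "0" in str(k):
            continue
        cand = f"{prefix}{k}"
        if cand in reserved:
            raise ValueError(f"generated id collides with reserved id {cand}")
        out.append(cand)
    return out


def _reference_rank(ref: tuple[str, str], priority: list[str], rhea_prefixes: frozenset[str]) -> tuple:
    prefix, local = ref
    is_rhea = 0 if prefix in rhea_prefixes or prefix.startswith("rhea") else 1
    try:
        p = priority.index(prefix)
    except ValueError:
        p = len(priority)
    return (is_rhea, p, prefix, local)


def build_reaction_namespace(
    reactions,
    mapping: dict[tuple[str, str], str],
    structures: dict[str, tuple[str | None, int | None]] | None = None,
    priority: list[str] | None = None,
) -> list[UnifiedReaction]:
    """Rewrite source reactions into the namespace and deduplicate them.

    Pipeline per reaction: id substitution with cancellation → proton
    balancing (only when the imbalance is proton-only and structures are
    known) → transported-proton relabelling → canonical key.  Reactions
    sharing a key become one entry; the reference member prefers a Rhea
    source, then the configured priority order; disagreeing member
    directions fold to BIDIRECTIONAL.  The empty-key group is emitted with
    ``empty=True`` and is meant to be excluded from mapped models.
    """
    structures = structures or {}
    priority = priority or []
    groups: dict[str, list] = {}
    for r in reactions:
        local_map = {t.met: mapping[(r.prefix, t.met)] for t in (*r.equation.left, *r.equation.right)}
        eq = rewrite_equation(r.equation, local_map)
        report = balance_check(eq, structures)
        if report.verdict is BalanceVerdict.PROTON_ONLY:
            eq = proton_balance(eq, report)
            report = balance_check(eq, structures)
        eq = classify_transported_protons(eq)
        key, flipped = canonical_key(eq)
        groups.setdefault(key, []).append(
            ((r.prefix, r.local_id), eq, _fold_direction(eq.direction, flipped), flipped, report)
        )

    rhea = frozenset()
    drafts = []
    for key, members in sorted(groups.items()):
        refs = sorted(m[0] for m in members)
        reference = min(refs, key=lambda ref: _reference_rank(ref, priority, rhea))
        direction = merge_directions(m[2] for m in members)
        # canonical orientation of the representative equation
        ref_eq, ref_flip = next((m[1], m[3]) for m in members if m[0] == reference)
        eq = ref_eq if not ref_flip else Equation(ref_eq.right, ref_eq.left, direction)
        eq = Equation(eq.left, eq.right, direction)
        report = next(m[4] for m in members if m[0] == reference)
        drafts.append((reference, key, eq, tuple(refs), report))

    drafts.sort(key=lambda d: d[0])
    ids = _zero_free_ids("MNXR", len(drafts), frozenset())
    out = [
        UnifiedReaction(
            mnx_id=mnx_id,
            equation=eq,
            key=key,
            members=members,
            reference=reference,
            empty=(key == EMPTY_KEY),
            balance=report,
        )
        for mnx_id, (reference, key, eq, members, report) in zip(ids, drafts)
    ]
    out.sort(key=lambda u: int(u.mnx_id[4:]))
    return out
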