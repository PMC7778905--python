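"""InChI layer handling and normalized structure keys.

The unified namespace merges metabolites that differ only in protonation
state, tautomeric form or isotopic labelling.  Standard InChI already folds
mobile-hydrogen tautomers into its ``/h`` layer, so the remaining policy
decisions are which layers to *ignore* when two structures are compared:

* ``/p`` (added/removed protons) and the hydrogen count of the formula —
  protonation;
* ``/q`` — formal charge (a protonation side effect);
* ``/i`` — isotopic labelling;
* ``/t /m /s /b`` — stereochemistry, kept by default but relaxable when a
  fully specified stereoisomer is compared with an unspecified one.

A :class:`StructureKey` is the comparable digest of an InChI under one such
policy; equal keys are the pass-1 merge criterion of the reconciliation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "InChILayers",
    "StructureKeyPolicy",
    "StructureKey",
    "InChIParseError",
    "parse_inchi",
    "reserialize",
    "structure_key",
    "similar_structures",
    "SimilarityVerdict",
    "DEFAULT_POLICY",
]


class InChIParseError(ValueError):
    """Raised when a string is not parseable as an InChI."""


# Layers that may appear at the top level of a standard InChI, in canonical
# serialization order.  The isotopic block (/i...) swallows everything that
# follows it, including its own /h, /t, /m, /s sublayers.
_LAYER_ORDER = ("c", "h", "q", "p", "b", "t", "m", "s")


@dataclass(frozen=True)
class InChILayers:
    """A standard InChI split into its slash-delimited layers."""

    version_tag: str
    formula: str
    connectivity: str | None = None
    h_layer: str | None = None
    charge: int = 0
    protonation: int = 0
    # verbatim /q and /p layer text (multi-component layers like ";+1" sum
    # to the integer fields but must reserialize losslessly)
    q_raw: str | None = None
    p_raw: str | None = None
    stereo_b: str | None = None
    stereo_t: str | None = None
    stereo_m: str | None = None
    stereo_s: str | None = None
    isotope: str | None = None
    unknown: tuple[str, ...] = ()
    raw: str = ""


_SIGNED = re.compile(r"^(?:(\d+)\*)?([+-]?\d+)$")


def _parse_int_layer(prefix: str, content: str) -> int:
    """Total of a /q or /p layer; components are ';'-separated and may carry
    an 'n*' multiplier; an empty component contributes 0."""
    total = 0
    for comp in content.split(";"):
        if not comp:
            continue
        m = _SIGNED.match(comp)
        if not m:
            raise InChIParseError(
                f"layer /{prefix} must contain integers, got {content!r}"
            )
        total += int(m.group(1) or 1) * int(m.group(2))
    return total


def parse_inchi(inchi: str) -> InChILayers:
    """Split an InChI string into layers.

    Absent layers stay ``None`` (``0`` for the integer /q and /p layers);
    layers not recognized at the top level are preserved verbatim in
    ``unknown`` so reserialization is lossless.
    """
    if not inchi.startswith("InChI="):
        raise InChIParseError(f"not an InChI (missing 'InChI=' prefix): {inchi!r}")
    body = inchi[len("InChI="):]
    parts = body.split("/")
    version = parts[0]
    if not re.fullmatch(r"1S?", version):
        raise InChIParseError(f"unsupported InChI version tag {version!r}")
    if len(parts) < 2 or not parts[1]:
        raise InChIParseError("missing formula layer")
    formula = parts[1]

    fields: dict[str, object] = {}
    unknown: list[str] = []
    i = 2
    while i < len(parts):
        layer = parts[i]
        if not layer:
            raise InChIParseError("empty layer (consecutive '/')")
        tag = layer[0]
        content = layer[1:]
        if tag == "i":
            # isotopic block: everything from here on belongs to it
            fields["isotope"] = "/".join(parts[i:])[1:]
            break
        if tag == "c":
            fields["connectivity"] = content
        elif tag == "h":
            fields["h_layer"] = content
        elif tag == "q":
            fields["charge"] = _parse_int_layer("q", content)
            fields["q_raw"] = content
        elif tag == "p":
            fields["protonation"] = _parse_int_layer("p", content)
            fields["p_raw"] = content
        elif tag == "b":
            fields["stereo_b"] = content
        elif tag == "t":
            fields["stereo_t"] = content
        elif tag == "m":
            fields["stereo_m"] = content
        elif tag == "s":
            fields["stereo_s"] = content
        else:
            unknown.append(layer)
        i += 1

    return InChILayers(
        version_tag=version,
        formula=formula,
        unknown=tuple(unknown),
        raw=inchi,
        **fields,  # type: ignore[arg-type]
    )


def reserialize(layers: InChILayers) -> str:
    """Rebuild the InChI string from parsed layers in canonical order.

    For standard InChIs this is the exact inverse of :func:`parse_inchi`.
    """
    out = [f"InChI={layers.version_tag}", layers.formula]
    if layers.connectivity is not None:
        out.append("c" + layers.connectivity)
    if layers.h_layer is not None:
        out.append("h" + layers.h_layer)
    if layers.q_raw is not None:
        out.append("q" + layers.q_raw)
    elif layers.charge != 0:
        out.append(f"q{layers.charge:+d}")
    if layers.p_raw is not None:
        out.append("p" + layers.p_raw)
    elif layers.protonation != 0:
        out.append(f"p{layers.protonation:+d}")
    if layers.stereo_b is not None:
        out.append("b" + layers.stereo_b)
    if layers.stereo_t is not None:
        out.append("t" + layers.stereo_t)
    if layers.stereo_m is not None:
        out.append("m" + layers.stereo_m)
    if layers.stereo_s is not None:
        out.append("s" + layers.stereo_s)
    out.extend(layers.unknown)
    if layers.isotope is not None:
        out.append("i" + layers.isotope)
    return "/".join(out)


@dataclass(frozen=True)
class StructureKeyPolicy:
    """Which InChI layers a structure key ignores."""

    drop_protonation: bool = True
    drop_isotopes: bool = True
    drop_stereo: bool = False
    drop_charge: bool = True

    @property
    def policy_id(self) -> str:
        flags = [
            "p" if self.drop_protonation else "",
            "i" if self.drop_isotopes else "",
            "x" if self.drop_stereo else "",
            "q" if self.drop_charge else "",
        ]
        return "drop:" + "".join(flags)


DEFAULT_POLICY = StructureKeyPolicy()


@dataclass(frozen=True)
class StructureKey:
    skeleton: str
    stereo: str
    policy_id: str


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_COMPONENT_MULT = re.compile(r"^(\d+)(.*)$")


def _elide_h(component: str) -> str:
    """Remove the H token from one Hill-formula component.

    Heavy atoms keep their counts; a trailing charge sign (non-standard but
    tolerated) is preserved.
    """
    pos = 0
    out = []
    for m in _FORMULA_TOKEN.finditer(component):
        if m.start() != pos:
            out.append(component[pos:m.start()])
        pos = m.end()
        if m.group(1) == "H":
            continue
        out.append(m.group(0))
    out.append(component[pos:])
    return "".join(out)


def _split_components(text: str | None, sep: str) -> list[str]:
    if text is None:
        return []
    expanded: list[str] = []
    for comp in text.split(sep):
        m = _COMPONENT_MULT.match(comp) if sep == "." else None
        if m and m.group(2):
            expanded.extend([m.group(2)] * int(m.group(1)))
        else:
            expanded.append(comp)
    return expanded


def structure_key(layers: InChILayers, policy: StructureKeyPolicy = DEFAULT_POLICY) -> StructureKey:
    """Compute the merge key of a parsed InChI under a layer policy.

    The skeleton pairs each formula component (H count elided) with its
    connectivity component and sorts the pairs, so component order in
    multi-component (salt) formulas cannot break equality.
    """
    formulas = _split_components(layers.formula, ".")
    conns = _split_components(layers.connectivity, ";")
    if len(conns) == len(formulas):
        pairs = [
            f"{_elide_h(f)}|{c}" for f, c in zip(formulas, conns)
        ]
    else:
        conn = layers.connectivity or ""
        pairs = [f"{_elide_h(f)}" for f in formulas]
        if conn:
            pairs = [p + "|" + conn for p in pairs]
    skeleton = ".".join(sorted(pairs))
    if not policy.drop_charge:
        skeleton += f"/q{layers.charge:+d}"
    if not policy.drop_protonation:
        skeleton += f"/p{layers.protonation:+d}/H{_total_h(layers.formula)}"
    if not policy.drop_isotopes and layers.isotope is not None:
        skeleton += "/i" + layers.isotope

    if policy.drop_stereo:
        stereo = ""
    else:
        chunks = []
        for tag, val in (
            ("b", layers.stereo_b),
            ("t", layers.stereo_t),
            ("m", layers.stereo_m),
            ("s", layers.stereo_s),
        ):
            if val is not None:
                chunks.append(f"{tag}{val}")
        stereo = "/".join(chunks)
    return StructureKey(skeleton=skeleton, stereo=stereo, policy_id=policy.policy_id)


def _total_h(formula: str) -> int:
    total = 0
    for comp in _split_components(formula, "."):
        for m in _FORMULA_TOKEN.finditer(comp):
            if m.group(1) == "H":
                total += int(m.group(2) or 1)
    return total


class SimilarityVerdict(Enum):
    IDENTICAL = "IDENTICAL"
    STEREO_RELAXED = "STEREO_RELAXED"
    DIFFERENT = "DIFFERENT"


def similar_structures(a: StructureKey, b: StructureKey) -> SimilarityVerdict:
    """Compare two structure keys computed under the same policy.

    IDENTICAL: skeleton and stereo both equal.  STEREO_RELAXED: equal
    skeletons with at least one empty stereo descriptor — a fully specified
    stereoisomer against an unspecified one.  Two *conflicting* fully
    specified stereo strings are DIFFERENT and must never be merged on
    context evidence alone.
    """
    if a.policy_id != b.policy_id:
        raise ValueError(
            f"structure keys computed under different policies: "
            f"{a.policy_id!r} vs {b.policy_id!r}"
        )
    if a.skeleton != b.skeleton:
        return SimilarityVerdict.DIFFERENT
    if a.stereo == b.stereo:
        return SimilarityVerdict.IDENTICAL
    if not a.stereo or not b.stereo:
        return SimilarityVerdict.STEREO_RELAXED
    return SimilarityVerdict.DIFFERENT
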