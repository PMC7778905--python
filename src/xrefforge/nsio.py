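"""TAB-delimited namespace distribution and source TSV I/O.

The distribution bundle follows the public MNXref flat-file layout closely
enough that the real files parse: four UTF-8 TSVs with a '#'-prefixed
header each —

* ``chem_prop.tsv``  — ID, name, reference, formula, charge, InChI
* ``chem_xref.tsv``  — source ("prefix:id"), ID
* ``reac_prop.tsv``  — ID, equation, direction, reference
* ``reac_xref.tsv``  — source, ID

Rows are sorted by ID (then source) so repeated writes are byte-identical.
Unknown trailing columns in files being read are ignored with a warning,
for forward compatibility with the real distribution.

Source databases live one directory per namespace prefix, with
``metabolites.tsv`` (id, names, formula, charge, inchi, xrefs) and
``reactions.tsv`` (id, equation, direction, xrefs).  Metabolite xrefs are
carried for provenance only; the reconciliation never reads them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .reacspace import (
    Direction,
    Equation,
    UnifiedReaction,
    BalanceReport,
    format_equation,
    parse_equation,
)
from .reconcile import NamespaceEntry, SourceMetabolite, SourceReaction

logger = logging.getLogger(__name__)

__all__ = [
    "write_sources",
    "read_sources",
    "write_distribution",
    "read_distribution",
    "write_conflicts",
]

CHEM_PROP_COLUMNS = ["ID", "name", "reference", "formula", "charge", "InChI"]
CHEM_XREF_COLUMNS = ["source", "ID"]
REAC_PROP_COLUMNS = ["ID", "equation", "direction", "reference"]
REAC_XREF_COLUMNS = ["source", "ID"]

_DIRECTION_CODE = {Direction.LR: "LR", Direction.RL: "RL", Direction.BIDIRECTIONAL: "B"}
_DIRECTION_OF = {v: k for k, v in _DIRECTION_CODE.items()}


def _mnx_sort_key(mnx_id: str) -> tuple:
    # numeric order; ties (MNXM1 vs MNXM01) put the balancing proton first
    digits = "".join(ch for ch in mnx_id if ch.isdigit())
    return (int(digits) if digits else 0, len(mnx_id), mnx_id)


# --------------------------------------------------------------------------
# source databases
# --------------------------------------------------------------------------

def write_sources(
    metabolites: list[SourceMetabolite],
    reactions: list[SourceReaction],
    out_dir: str | Path,
) -> None:
    out_dir = Path(out_dir)
    prefixes = sorted({m.prefix for m in metabolites} | {r.prefix for r in reactions})
    for prefix in prefixes:
        d = out_dir / prefix
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "metabolites.tsv", "w", encoding="utf-8") as fh:
            fh.write("#id\tnames\tformula\tcharge\tinchi\txrefs\n")
            for m in sorted((m for m in metabolites if m.prefix == prefix), key=lambda m: m.local_id):
                fh.write("\t".join([
                    m.local_id,
                    "|".join(m.names),
                    m.formula or "",
                    "" if m.charge is None else str(m.charge),
                    m.inchi or "",
                    "|".join(f"{p}:{i}" for p, i in m.xrefs),
                ]) + "\n")
        with open(d / "reactions.tsv", "w", encoding="utf-8") as fh:
            fh.write("#id\tequation\tdirection\txrefs\n")
            for r in sorted((r for r in reactions if r.prefix == prefix), key=lambda r: r.local_id):
                fh.write("\t".join([
                    r.local_id,
                    format_equation(r.equation),
                    _DIRECTION_CODE[r.direction],
                    "|".join(f"{p}:{i}" for p, i in r.xrefs),
                ]) + "\n")


def _split_refs(cell: str) -> tuple[tuple[str, str], ...]:
    if not cell:
        return ()
    return tuple(tuple(x.split(":", 1)) for x in cell.split("|"))  # type: ignore[return-value]


def read_sources(src_dir: str | Path) -> tuple[list[SourceMetabolite], list[SourceReaction]]:
    src_dir = Path(src_dir)
    metabolites: list[SourceMetabolite] = []
    reactions: list[SourceReaction] = []
    for d in sorted(p for p in src_dir.iterdir() if p.is_dir()):
        prefix = d.name
        met_file = d / "metabolites.tsv"
        if met_file.exists():
            for row in _read_rows(met_file, 6):
                local_id, names, formula, charge, inchi, xrefs = row
                metabolites.append(SourceMetabolite(
                    prefix=prefix,
                    local_id=local_id,
                    names=tuple(n for n in names.split("|") if n),
                    formula=formula or None,
                    charge=int(charge) if charge else None,
                    inchi=inchi or None,
                    xrefs=_split_refs(xrefs),
                ))
        rxn_file = d / "reactions.tsv"
        if rxn_file.exists():
            for row in _read_rows(rxn_file, 4):
                local_id, equation, direction, xrefs = row
                eq = parse_equation(equation)
                reactions.append(SourceReaction(
                    prefix=prefix,
                    local_id=local_id,
                    equation=Equation(eq.left, eq.right, _DIRECTION_OF[direction]),
                    direction=_DIRECTION_OF[direction],
                    xrefs=_split_refs(xrefs),
                ))
    return metabolites, reactions


def _read_rows(path: Path, ncols: int):
    warned = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) > ncols and not warned:
                logger.warning("%s:%d: %d extra column(s) ignored", path, lineno, len(cells) - ncols)
                warned = True
            cells = (cells + [""] * ncols)[:ncols]
            yield cells


# --------------------------------------------------------------------------
# distribution bundle
# --------------------------------------------------------------------------

def write_distribution(
    entries: list[NamespaceEntry],
    reactions: list[UnifiedReaction],
    out_dir: str | Path,
) -> None:
    """Write the four-file TAB-delimited distribution; deterministic output."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with open(out_dir / "chem_prop.tsv", "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(CHEM_PROP_COLUMNS) + "\n")
        for e in sorted(entries, key=lambda e: _mnx_sort_key(e.mnx_id)):
            fh.write("\t".join([
                e.mnx_id,
                e.name,
                f"{e.reference[0]}:{e.reference[1]}",
                e.formula or "",
                "" if e.charge is None else str(e.charge),
                e.structure or "",
            ]) + "\n")

    with open(out_dir / "chem_xref.tsv", "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(CHEM_XREF_COLUMNS) + "\n")
        rows = [
            (f"{p}:{i}", e.mnx_id)
            for e in entries for (p, i) in sorted(e.members)
        ]
        for source, mnx_id in sorted(rows, key=lambda r: (_mnx_sort_key(r[1]), r[0])):
            fh.write(f"{source}\t{mnx_id}\n")

    with open(out_dir / "reac_prop.tsv", "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(REAC_PROP_COLUMNS) + "\n")
        for r in sorted(reactions, key=lambda r: _mnx_sort_key(r.mnx_id)):
            fh.write("\t".join([
                r.mnx_id,
                format_equation(Equation(r.equation.left, r.equation.right, Direction.BIDIRECTIONAL))
                if r.empty is False else "=",
                _DIRECTION_CODE[r.equation.direction],
                f"{r.reference[0]}:{r.reference[1]}",
            ]) + "\n")

    with open(out_dir / "reac_xref.tsv", "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(REAC_XREF_COLUMNS) + "\n")
        rows = [
            (f"{p}:{i}", r.mnx_id)
            for r in reactions for (p, i) in sorted(r.members)
        ]
        for source, mnx_id in sorted(rows, key=lambda r: (_mnx_sort_key(r[1]), r[0])):
            fh.write(f"{source}\t{mnx_id}\n")


def read_distribution(path: str | Path) -> tuple[list[NamespaceEntry], list[UnifiedReaction]]:
    """Read a distribution bundle back; inverse of :func:`write_distribution`.

    Raises on a cross-reference pointing at a missing ID; warns on (and
    ignores) unknown trailing columns.
    """
    path = Path(path)

    chem_members: dict[str, set] = {}
    for source, mnx_id in _read_rows(path / "chem_xref.tsv", 2):
        prefix, local = source.split(":", 1)
        chem_members.setdefault(mnx_id, set()).add((prefix, local))

    entries: list[NamespaceEntry] = []
    chem_ids: set[str] = set()
    for row in _read_rows(path / "chem_prop.tsv", 6):
        mnx_id, name, reference, formula, charge, inchi = row
        chem_ids.add(mnx_id)
        p, i = reference.split(":", 1)
        entries.append(NamespaceEntry(
            mnx_id=mnx_id,
            members=frozenset(chem_members.get(mnx_id, set())),
            reference=(p, i),
            structure=inchi or None,
            name=name,
            formula=formula or None,
            charge=int(charge) if charge else None,
        ))
    for mnx_id in chem_members:
        if mnx_id not in chem_ids:
            raise ValueError(f"chem_xref.tsv references unknown ID {mnx_id}")

    reac_members: dict[str, set] = {}
    for source, mnx_id in _read_rows(path / "reac_xref.tsv", 2):
        prefix, local = source.split(":", 1)
        reac_members.setdefault(mnx_id, set()).add((prefix, local))

    reactions: list[UnifiedReaction] = []
    reac_ids: set[str] = set()
    from .reacspace import canonical_key, EMPTY_KEY

    for row in _read_rows(path / "reac_prop.tsv", 4):
        mnx_id, equation, direction, reference = row
        reac_ids.add(mnx_id)
        p, i = reference.split(":", 1)
        if equation == "=":
            eq = Equation((), (), _DIRECTION_OF[direction])
        else:
            parsed = parse_equation(equation)
            eq = Equation(parsed.left, parsed.right, _DIRECTION_OF[direction])
        key, _ = canonical_key(eq)
        reactions.append(UnifiedReaction(
            mnx_id=mnx_id,
            equation=eq,
            key=key,
            members=tuple(sorted(reac_members.get(mnx_id, set()))),
            reference=(p, i),
            empty=(key == EMPTY_KEY),
            balance=BalanceReport(),
        ))
    for mnx_id in reac_members:
        if mnx_id not in reac_ids:
            raise ValueError(f"reac_xref.tsv references unknown ID {mnx_id}")

    return entries, reactions


def write_conflicts(conflicts, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#kind\tmembers\treaction\tresolution\n")
        for c in sorted(conflicts, key=lambda c: (c.kind.value, sorted(c.members))):
            members = "|".join(f"{p}:{i}" for p, i in sorted(c.members))
            rxn = f"{c.reaction[0]}:{c.reaction[1]}" if c.reaction else ""
            fh.write(f"{c.kind.value}\t{members}\t{rxn}\t{c.resolution.value}\n")
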