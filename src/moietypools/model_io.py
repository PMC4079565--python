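"""Reading, writing and editing of stoichiometric models with exact rational arithmetic.

A stoichiometric matrix is stored as a sparse map ``(metabolite, reaction) ->
Fraction``.  Coefficients are parsed from their decimal/rational string
representation straight into :class:`fractions.Fraction`; they never pass
through a binary float, so a coefficient written ``0.02`` is stored as the
exact rational 1/50.  This matters because conserved-pool identification is an
exact integer problem: float round-off can create or destroy left-kernel
vectors.

Supported input formats:

* ``triplets`` — whitespace-separated ``metabolite reaction coefficient``
  lines, ``#`` comments, UTF-8.
* ``bigg_json`` — BiGG-style model JSON (``metabolites``/``reactions`` lists).
* ``sbml`` — SBML Level 2/3, parsed at the XML level so that stoichiometry
  attribute strings are converted exactly; species flagged with
  ``boundaryCondition="true"`` are treated as external and dropped.

Pool reports mirror the field's table convention: ``"met1 + (2) met2"`` with a
``(k)`` prefix whenever a coefficient exceeds 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import lcm
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

__all__ = [
    "StoichiometricModel",
    "MediumSpec",
    "FormatError",
    "ConfigurationError",
    "read_model",
    "apply_medium",
    "clear_denominators",
    "write_pools",
    "read_pools",
    "format_pool",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in its declared format."""


class ConfigurationError(ValueError):
    """Raised when a medium/biomass specification references unknown ids."""


@dataclass
class StoichiometricModel:
    """Sparse exact-rational stoichiometric matrix with named rows/columns.

    Rows are metabolites, columns are reactions (exchange fluxes included);
    substrates carry negative coefficients, products positive ones.
    """

    metabolite_ids: List[str]
    reaction_ids: List[str]
    coeff: Dict[Tuple[str, str], Fraction]
    exchange_ids: Set[str] = field(default_factory=set)
    biomass_id: Optional[str] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        mets = set(self.metabolite_ids)
        rxns = set(self.reaction_ids)
        if len(mets) != len(self.metabolite_ids):
            raise ValueError("duplicate metabolite ids")
        if len(rxns) != len(self.reaction_ids):
            raise ValueError("duplicate reaction ids")
        for (m, r), v in self.coeff.items():
            if m not in mets or r not in rxns:
                raise ValueError(f"coefficient references undeclared id: ({m}, {r})")
            if not isinstance(v, Fraction):
                raise TypeError(f"coefficient for ({m}, {r}) is not a Fraction")
        if self.exchange_ids - rxns:
            raise ValueError("exchange_ids not a subset of reaction_ids")

    # -- derived views -----------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def columns(self) -> Dict[str, Dict[str, Fraction]]:
        """reaction id -> {metabolite id -> coefficient} (nonzeros only)."""
        cols: Dict[str, Dict[str, Fraction]] = {r: {} for r in self.reaction_ids}
        for (m, r), v in self.coeff.items():
            if v:
                cols[r][m] = v
        return cols

    def rows(self) -> Dict[str, Dict[str, Fraction]]:
        """metabolite id -> {reaction id -> coefficient} (nonzeros only)."""
        rws: Dict[str, Dict[str, Fraction]] = {m: {} for m in self.metabolite_ids}
        for (m, r), v in self.coeff.items():
            if v:
                rws[m][r] = v
        return rws

    def is_integer(self) -> bool:
        return all(v.denominator == 1 for v in self.coeff.values())


@dataclass
class MediumSpec:
    """Which exchange columns to keep: all (rich) or a named subset."""

    mode: str = "rich"  # rich | minimal | custom
    kept_exchanges: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("rich", "minimal", "custom"):
            raise ValueError(f"unknown medium mode: {self.mode!r}")


def detect_exchanges(
    metabolite_ids: Sequence[str],
    reaction_ids: Sequence[str],
    coeff: Dict[Tuple[str, str], Fraction],
    extra: Iterable[str] = (),
) -> Set[str]:
    """Exchange reactions = columns with exactly one nonzero entry, plus any
    reactions flagged by the source format's boundary convention (`extra`)."""
    counts: Dict[str, int] = {r: 0 for r in reaction_ids}
    for (m, r), v in coeff.items():
        if v:
            counts[r] += 1
    out = {r for r, n in counts.items() if n == 1}
    out.update(extra)
    return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _parse_rational(text: str, where: str) -> Fraction:
    """Parse a decimal or rational literal exactly (never via a float)."""
    try:
        return Fraction(text)
    except (ValueError, ZeroDivisionError) as exc:
        raise FormatError(f"{where}: cannot parse coefficient {text!r}") from exc


def _read_triplets(path: str) -> StoichiometricModel:
    mets: List[str] = []
    rxns: List[str] = []
    seen_m: Set[str] = set()
    seen_r: Set[str] = set()
    coeff: Dict[Tuple[str, str], Fraction] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'metabolite reaction coefficient'")
            m, r, c = parts
            if (m, r) in coeff:
                raise FormatError(f"{path}:{lineno}: duplicate entry for ({m}, {r})")
            if m not in seen_m:
                seen_m.add(m)
                mets.append(m)
            if r not in seen_r:
                seen_r.add(r)
                rxns.append(r)
            coeff[(m, r)] = _parse_rational(c, f"{path}:{lineno}")
    if not mets or not rxns:
        raise FormatError(f"{path}: no stoichiometric entries found")
    return StoichiometricModel(
        metabolite_ids=mets,
        reaction_ids=rxns,
        coeff=coeff,
        exchange_ids=detect_exchanges(mets, rxns, coeff),
        provenance=f"triplets:{path}",
    )


def _read_bigg_json(path: str) -> StoichiometricModel:
    # parse_float receives the raw decimal string -> exact Fraction
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh, parse_float=Fraction)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    try:
        mets = [m["id"] for m in doc["metabolites"]]
        rxn_docs = doc["reactions"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a BiGG-style model JSON ({exc})") from exc
    rxns = [r["id"] for r in rxn_docs]
    met_set = set(mets)
    coeff: Dict[Tuple[str, str], Fraction] = {}
    for r in rxn_docs:
        rid = r["id"]
        for m, v in r.get("metabolites", {}).items():
            if m not in met_set:
                raise FormatError(f"{path}: reaction {rid} references unknown metabolite {m}")
            frac = v if isinstance(v, Fraction) else Fraction(v)
            if frac:
                coeff[(m, rid)] = frac
    biomass = [r for r in rxns if "biomass" in r.lower()]
    return StoichiometricModel(
        metabolite_ids=mets,
        reaction_ids=rxns,
        coeff=coeff,
        exchange_ids=detect_exchanges(mets, rxns, coeff),
        biomass_id=biomass[0] if len(biomass) == 1 else None,
        provenance=f"bigg_json:{path}",
    )


def _read_sbml(path: str) -> StoichiometricModel:
    from lxml import etree

    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: invalid XML ({exc})") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise FormatError(f"{path}: root element is <{root.tag}>, not <sbml>")
    ns = etree.QName(root).namespace

    def q(tag: str) -> str:
        return f"{{{ns}}}{tag}"

    model_el = root.find(q("model"))
    if model_el is None:
        raise FormatError(f"{path}: no <model> element")

    boundary: Set[str] = set()
    mets: List[str] = []
    species_list = model_el.find(q("listOfSpecies"))
    if species_list is None:
        raise FormatError(f"{path}: no <listOfSpecies>")
    for sp in species_list.findall(q("species")):
        sid = sp.get("id")
        if sid is None:
            raise FormatError(f"{path}: species without id")
        if sp.get("boundaryCondition", "false").lower() == "true":
            boundary.add(sid)
        else:
            mets.append(sid)
    met_set = set(mets)

    rxns: List[str] = []
    coeff: Dict[Tuple[str, str], Fraction] = {}
    rxn_list = model_el.find(q("listOfReactions"))
    if rxn_list is None:
        raise FormatError(f"{path}: no <listOfReactions>")
    for rx in rxn_list.findall(q("reaction")):
        rid = rx.get("id")
        if rid is None:
            raise FormatError(f"{path}: reaction without id")
        rxns.append(rid)
        for side, sign in ((q("listOfReactants"), -1), (q("listOfProducts"), 1)):
            lst = rx.find(side)
            if lst is None:
                continue
            for ref in lst.findall(q("speciesReference")):
                sid = ref.get("species")
                if sid is None:
                    raise FormatError(f"{path}: reaction {rid}: speciesReference without species")
                if sid in boundary:
                    continue  # external species: the row is not part of the balance
                if sid not in met_set:
                    raise FormatError(f"{path}: reaction {rid} references unknown species {sid}")
                stoich = _parse_rational(ref.get("stoichiometry", "1"), f"{path}:{rid}")
                coeff[(sid, rid)] = coeff.get((sid, rid), Fraction(0)) + sign * stoich

    coeff = {k: v for k, v in coeff.items() if v}
    # a reaction that touched a boundary species is an exchange by convention
    boundary_rxns = set()
    for rx in rxn_list.findall(q("reaction")):
        for side in (q("listOfReactants"), q("listOfProducts")):
            lst = rx.find(side)
            if lst is None:
                continue
            if any(ref.get("species") in boundary for ref in lst.findall(q("speciesReference"))):
                boundary_rxns.add(rx.get("id"))
    biomass = [r for r in rxns if "biomass" in r.lower()]
    return StoichiometricModel(
        metabolite_ids=mets,
        reaction_ids=rxns,
        coeff=coeff,
        exchange_ids=detect_exchanges(mets, rxns, coeff, extra=boundary_rxns),
        biomass_id=biomass[0] if len(biomass) == 1 else None,
        provenance=f"sbml:{path}",
    )


_READERS = {"triplets": _read_triplets, "bigg_json": _read_bigg_json, "sbml": _read_sbml}


def read_model(path: str, format: str) -> StoichiometricModel:
    """Read a stoichiometric model; coefficients are stored exactly.

    Parameters
    ----------
    path : str
        Input file.
    format : {"triplets", "bigg_json", "sbml"}
        Declared format.
    """
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_READERS)}") from None
    return reader(path)


# ---------------------------------------------------------------------------
# Medium edits
# ---------------------------------------------------------------------------


def apply_medium(
    model: StoichiometricModel,
    medium: MediumSpec,
    drop_biomass: bool = False,
) -> StoichiometricModel:
    """Restrict the exchange columns of a model to a medium and optionally
    delete the biomass column.

    Conservation laws are direction-independent, so closing a medium removes
    the whole exchange column.  Metabolite rows are never deleted.
    """
    if medium.mode == "rich":
        kept = set(model.exchange_ids)
    else:
        kept = set(medium.kept_exchanges)
        missing = kept - model.exchange_ids
        if missing:
            raise ConfigurationError(
                "kept exchanges absent from model: " + ", ".join(sorted(missing))
            )
    drop: Set[str] = model.exchange_ids - kept
    if drop_biomass:
        if model.biomass_id is None:
            raise ConfigurationError("drop_biomass requested but model has no biomass id")
        drop.add(model.biomass_id)
    rxns = [r for r in model.reaction_ids if r not in drop]
    if not rxns:
        raise ConfigurationError("medium edit removed every reaction column")
    coeff = {(m, r): v for (m, r), v in model.coeff.items() if r not in drop}
    return StoichiometricModel(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=rxns,
        coeff=coeff,
        exchange_ids=model.exchange_ids & set(rxns),
        biomass_id=None if drop_biomass else model.biomass_id,
        provenance=model.provenance + f"|medium:{medium.mode}",
    )


def clear_denominators(model: StoichiometricModel) -> StoichiometricModel:
    """Scale each reaction column by the LCM of its entries' denominators.

    Positive per-column scaling leaves the conserved-pool solution set
    unchanged (the balance constraint is per-column and homogeneous), so the
    resulting all-integer matrix is interchangeable with the original for
    every downstream computation.
    """
    cols = model.columns()
    scale: Dict[str, int] = {}
    for r, col in cols.items():
        denoms = [v.denominator for v in col.values()]
        scale[r] = lcm(*denoms) if denoms else 1
    if all(s == 1 for s in scale.values()):
        return model
    coeff = {(m, r): v * scale[r] for (m, r), v in model.coeff.items()}
    return StoichiometricModel(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=list(model.reaction_ids),
        coeff=coeff,
        exchange_ids=set(model.exchange_ids),
        biomass_id=model.biomass_id,
        provenance=model.provenance + "|integerized",
    )


# ---------------------------------------------------------------------------
# Pool reports
# ---------------------------------------------------------------------------


def format_pool(coeffs: Dict[str, int]) -> str:
    """Human-readable formula: '+'-joined species, '(k)' prefix for k>1."""
    parts = []
    for m in sorted(coeffs):
        k = coeffs[m]
        parts.append(m if k == 1 else f"({k}) {m}")
    return " + ".join(parts)


def write_pools(basis, path: str, format: str = "tsv") -> None:
    """Write a pool basis as TSV (id, size, formula) or JSON."""
    pools = list(basis.pools) if hasattr(basis, "pools") else list(basis)
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pool_id\tsize\tformula\n")
            for i, p in enumerate(pools, 1):
                fh.write(f"{i}\t{p.size}\t{format_pool(p.coeffs_dict)}\n")
    elif format == "json":
        doc = [
            {"pool_id": i, "size": p.size,
             "coeffs": {m: k for m, k in sorted(p.coeffs_dict.items())}}
            for i, p in enumerate(pools, 1)
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown pool report format {format!r}")


def read_pools(path: str, format: str = "tsv") -> List[Dict[str, int]]:
    """Read a pool report back into coefficient maps (round-trip of write_pools)."""
    out: List[Dict[str, int]] = []
    if format == "tsv":
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("pool_id"):
                raise FormatError(f"{path}: not a pool report")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                _, _, formula = line.split("\t")
                coeffs: Dict[str, int] = {}
                for term in formula.split(" + "):
                    term = term.strip()
                    if term.startswith("("):
                        k_str, m = term[1:].split(") ", 1)
                        coeffs[m] = int(k_str)
                    elif term:
                        coeffs[term] = 1
                out.append(coeffs)
    elif format == "json":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        out = [{m: int(k) for m, k in entry["coeffs"].items()} for entry in doc]
    else:
        raise ValueError(f"unknown pool report format {format!r}")
    return out
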