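"""Model and run-configuration file formats.

The model format is deliberately plain: a JSON document

.. code-block:: json

    {"species":   [{"name": "A", "initial_count": 1}, ...],
     "reactions": [{"type": 2, "reactants": ["A", "B"],
                    "products": ["C"], "k": 0.5}, ...]}

or its TSV twin with one record per row (``S name count`` /
``R type reactants products k`` with '+'-joined species lists).  Species
names are arbitrary strings; internal indices are dense and 0-based in
file order.  Writing is canonical, so write-read-write is byte stable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .network_model import (
    InvalidModelError,
    ReactionNetwork,
    Species,
    reaction_from_lists,
    validate_network,
)

__all__ = [
    "ModelParseError",
    "read_model",
    "write_model",
    "RunConfig",
    "write_provenance",
]

_REACTANTS_PER_TYPE = {1: 1, 2: 2, 3: 2}


class ModelParseError(ValueError):
    """A model file is malformed; the message carries line/field context."""


def _products_of(reaction, names: list[str]) -> list[str]:
    """Reconstruct the product multiset from net deltas + reactants."""
    consumed: dict[int, int] = {}
    for s in reaction.reactant_indices:
        consumed[s] = consumed.get(s, 0) + 1
    out: list[str] = []
    for s, d in reaction.stoich:
        n = d + consumed.get(s, 0)
        out.extend([names[s]] * n)
    for s, c in consumed.items():
        if s not in dict(reaction.stoich):
            # cannot happen for valid reactions (net-zero is rejected)
            raise InvalidModelError(f"reaction {reaction.index}: inconsistent stoichiometry")
    return out


def _build_network(species_rows, reaction_rows, where) -> ReactionNetwork:
    species = []
    index_of: dict[str, int] = {}
    for i, (name, count) in enumerate(species_rows):
        if name in index_of:
            raise ModelParseError(f"{where}: duplicate species name {name!r}")
        index_of[name] = i
        try:
            species.append(Species(i, name, int(count)))
        except (ValueError, InvalidModelError) as err:
            raise ModelParseError(f"{where}: species {name!r}: {err}") from err
    reactions = []
    for m, (rtype, reactants, products, k) in enumerate(reaction_rows):
        try:
            rtype = int(rtype)
        except ValueError as err:
            raise ModelParseError(f"{where}: reaction {m}: bad type {rtype!r}") from err
        want = _REACTANTS_PER_TYPE.get(rtype)
        if want is None:
            raise ModelParseError(f"{where}: reaction {m}: unknown type {rtype}")
        if len(reactants) != want:
            raise ModelParseError(
                f"{where}: reaction {m}: type {rtype} takes {want} reactant(s), "
                f"got {len(reactants)}"
            )
        for name in list(reactants) + list(products):
            if name not in index_of:
                raise ModelParseError(
                    f"{where}: reaction {m}: unknown species name {name!r}"
                )
        try:
            reactions.append(
                reaction_from_lists(
                    m,
                    rtype,
                    [index_of[n] for n in reactants],
                    [index_of[n] for n in products],
                    float(k),
                )
            )
        except (ValueError, InvalidModelError) as err:
            raise ModelParseError(f"{where}: reaction {m}: {err}") from err
    try:
        network = ReactionNetwork(species, reactions)
    except InvalidModelError as err:
        raise ModelParseError(f"{where}: {err}") from err
    problems = validate_network(network)
    if problems:
        raise ModelParseError(f"{where}: invalid model: " + "; ".join(problems))
    return network


def read_model(path) -> ReactionNetwork:
    """Read a network from a ``.json`` or ``.tsv`` model file."""
    path = Path(path)
    if path.suffix == ".tsv":
        return _read_tsv(path)
    return _read_json(path)


def _read_json(path: Path) -> ReactionNetwork:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ModelParseError(f"{path}: line {err.lineno}: {err.msg}") from err
    if not isinstance(doc, dict) or "species" not in doc or "reactions" not in doc:
        raise ModelParseError(f"{path}: expected top-level 'species' and 'reactions'")
    species_rows = []
    for row in doc["species"]:
        try:
            species_rows.append((row["name"], row["initial_count"]))
        except (KeyError, TypeError) as err:
            raise ModelParseError(f"{path}: species entry {row!r}: {err}") from err
    reaction_rows = []
    for row in doc["reactions"]:
        try:
            reaction_rows.append(
                (row["type"], row["reactants"], row.get("products", []), row["k"])
            )
        except (KeyError, TypeError) as err:
            raise ModelParseError(f"{path}: reaction entry {row!r}: {err}") from err
    return _build_network(species_rows, reaction_rows, str(path))


def _read_tsv(path: Path) -> ReactionNetwork:
    species_rows = []
    reaction_rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        tag = parts[0]
        if tag == "S" and len(parts) == 3:
            species_rows.append((parts[1], parts[2]))
        elif tag == "R" and len(parts) == 5:
            reactants = parts[2].split("+") if parts[2] != "-" else []
            products = parts[3].split("+") if parts[3] != "-" else []
            reaction_rows.append((parts[1], reactants, products, parts[4]))
        else:
            raise ModelParseError(f"{path}: line {lineno}: unrecognized record {line!r}")
    return _build_network(species_rows, reaction_rows, str(path))


def write_model(network: ReactionNetwork, path) -> None:
    """Write a network to ``.json`` or ``.tsv`` (chosen by extension)."""
    path = Path(path)
    names = network.species_names
    if path.suffix == ".tsv":
        lines = ["# blockssa model"]
        for s in network.species:
            lines.append(f"S\t{s.name}\t{s.count}")
        for r in network.reactions:
            reactants = "+".join(names[i] for i in r.reactant_indices)
            products = "+".join(_products_of(r, names)) or "-"
            lines.append(f"R\t{r.rtype}\t{reactants}\t{products}\t{r.rate_constant!r}")
        path.write_text("\n".join(lines) + "\n")
        return
    doc = {
        "species": [
            {"name": s.name, "initial_count": s.count} for s in network.species
        ],
        "reactions": [
            {
                "type": r.rtype,
                "reactants": [names[i] for i in r.reactant_indices],
                "products": _products_of(r, names),
                "k": r.rate_constant,
            }
            for r in network.reactions
        ],
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")


@dataclass
class RunConfig:
    """Everything a run needs; serializes to/from JSON for provenance.

    CLI flags override file values field by field.
    """

    model: str | None = None
    family: str | None = None
    N: int | None = None
    M: int | None = None
    method: str = "blocked"
    t_final: float = 1.0
    record_dt: float = 0.01
    recorded_species: list[int] | None = None
    realizations: int = 1
    base_seed: int = 0
    blocks: int | None = None
    block_size: int | None = None
    chunk_size: int = 128
    refresh_interval: int | None = 10_000
    rel_tol: float | None = 1e-9
    output: str | None = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ModelParseError(f"{path}: unknown config fields {sorted(unknown)}")
        return cls(**doc)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")


def write_provenance(path, config: RunConfig, extra: dict | None = None) -> None:
    """Record the full run description next to its outputs."""
    from . import __version__

    doc = {
        "blockssa_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
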