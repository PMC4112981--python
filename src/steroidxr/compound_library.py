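"""Compound structures and packaged assay-panel fixtures.

This module reads chemical structures (SMILES line files and SDF V2000),
standardizes them for 2D similarity work, and serves the packaged panel of
steroid/steroidal compounds with their measured cross-reactivities and
published plasma-concentration ranges on the five packaged immunoassays
(cortisol, DHEA sulfate, estradiol, progesterone, testosterone).

Standardization deliberately discards information that structural-key
similarity cannot see: counterions (largest covalent fragment is kept),
stereochemistry (2D keys do not distinguish diastereomers or enantiomers)
and charge state (structures are neutralized where chemically valid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import Descriptors, rdmolops
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

log = logging.getLogger(__name__)

# RDKit is chatty on stderr during sanitization; route through warnings only.
RDLogger.DisableLog("rdApp.info")

PACKAGED_ASSAYS = ("cortisol", "dhea_sulfate", "estradiol", "progesterone", "testosterone")


class CompoundError(ValueError):
    """Raised for unparsable or structurally invalid compound records."""


@dataclass(frozen=True)
class Compound:
    """A named 2D structure.

    ``structure`` is an RDKit mol (the connection table); ``source_smiles``
    is the string as read. ``standardized`` records whether the molecule has
    been through :func:`standardize`.
    """

    name: str
    structure: Chem.Mol
    source_smiles: str
    standardized: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise CompoundError("compound name must be non-empty")

    @property
    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.structure)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        flag = "standardized" if self.standardized else "raw"
        return f"Compound({self.name!r}, {self.canonical_smiles!r}, {flag})"


@dataclass(frozen=True)
class ReferenceInterval:
    """Target-analyte reference interval (ng/mL) for one population."""

    population: str
    low: float | None
    high: float

    def __post_init__(self) -> None:
        if self.low is not None and self.high < self.low:
            raise ValueError(f"interval {self.population!r}: high < low")
        if self.high <= 0:
            raise ValueError(f"interval {self.population!r}: high must be > 0")


@dataclass(frozen=True)
class AssayDefinition:
    """One immunoassay: its target hapten, challenge spike and intervals."""

    assay_name: str
    target_compound: Compound
    spike_concentration: float  # ng/mL of test compound added
    reference_intervals: tuple[ReferenceInterval, ...]

    def __post_init__(self) -> None:
        if self.spike_concentration <= 0:
            raise ValueError("spike_concentration must be > 0")


@dataclass(frozen=True)
class PlasmaRange:
    """Published serum/plasma concentration interval for one population.

    ``low`` may be absent (many sources report only "up to X ng/mL").
    """

    compound_name: str
    population: str
    low: float | None
    high: float
    citation: str = ""

    def __post_init__(self) -> None:
        if self.high <= 0:
            raise ValueError("plasma high bound must be > 0")
        if self.low is not None and self.high < self.low:
            raise ValueError("plasma high bound must be >= low bound")


def _mol_from_smiles(smiles: str, context: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CompoundError(f"unparsable SMILES at {context}: {smiles!r}")
    return mol


def read_smiles_file(path: str | Path) -> list[Compound]:
    """Read a SMILES line file: ``SMILES<whitespace>name`` per line.

    Blank lines and ``#`` comments are skipped. The name is everything after
    the first whitespace, so multi-word names are allowed. Compounds are
    returned unstandardized, in input order.

    Raises
    ------
    CompoundError
        For unparsable SMILES (with the 1-based line number) or duplicate
        names.
    """
    path = Path(path)
    compounds: list[Compound] = []
    seen: set[str] = set()
    errors: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) < 2:
            errors.append(f"line {lineno}: missing name")
            continue
        smiles, name = parts[0], parts[1].strip()
        try:
            mol = _mol_from_smiles(smiles, f"line {lineno}")
        except CompoundError as exc:
            errors.append(str(exc))
            continue
        if name in seen:
            raise CompoundError(f"duplicate compound name {name!r} at line {lineno}")
        seen.add(name)
        compounds.append(Compound(name=name, structure=mol, source_smiles=smiles))
    if errors:
        raise CompoundError("; ".join(errors))
    return compounds


def write_smiles_file(compounds: Iterable[Compound], path: str | Path) -> None:
    """Write compounds back out in the same ``SMILES name`` line dialect."""
    lines = [f"{c.canonical_smiles}\t{c.name}" for c in compounds]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sdf_file(path: str | Path) -> list[Compound]:
    """Read an SDF (V2000) file; the molecule title or a name field names each record."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    compounds: list[Compound] = []
    seen: set[str] = set()
    for idx, mol in enumerate(supplier, start=1):
        if mol is None:
            raise CompoundError(f"unparsable SDF record {idx}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not name:
            for prop in ("name", "NAME", "Name"):
                if mol.HasProp(prop):
                    name = mol.GetProp(prop)
                    break
        if not name:
            raise CompoundError(f"SDF record {idx} has no name field")
        if name in seen:
            raise CompoundError(f"duplicate compound name {name!r} in SDF record {idx}")
        seen.add(name)
        compounds.append(Compound(name=name, structure=mol, source_smiles=Chem.MolToSmiles(mol)))
    return compounds


_uncharger = rdMolStandardize.Uncharger()


def standardize(compound: Compound) -> Compound:
    """Standardize a compound for structural-key fingerprinting.

    Keeps the largest covalent fragment (heavy-atom count, ties broken by
    molecular weight), removes all stereo descriptors, and neutralizes
    protonation states where chemically valid. Idempotent.
    """
    frags = rdmolops.GetMolFrags(compound.structure, asMols=True, sanitizeFrags=True)
    if not frags:
        raise CompoundError(f"{compound.name}: empty structure after fragment split")
    parent = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Descriptors.MolWt(m)))
    if len(frags) > 1:
        log.info("%s: kept largest of %d fragments", compound.name, len(frags))
    parent = Chem.Mol(parent)
    Chem.RemoveStereochemistry(parent)
    parent = _uncharger.uncharge(parent)
    Chem.SanitizeMol(parent)
    # re-canonicalize so equality of canonical SMILES == graph isomorphism
    parent = Chem.MolFromSmiles(Chem.MolToSmiles(parent))
    if parent is None or parent.GetNumHeavyAtoms() == 0:
        raise CompoundError(f"{compound.name}: empty structure after standardization")
    return replace(compound, structure=parent, standardized=True)


# ---------------------------------------------------------------------------
# Packaged fixtures (transcribed panel tables + curated structures)
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("steroidxr.data").joinpath(name)))


def load_compound_library(standardized: bool = True) -> dict[str, Compound]:
    """The packaged, curated structure library keyed by compound name."""
    compounds = read_smiles_file(_data_path("compounds.smi"))
    if standardized:
        compounds = [standardize(c) for c in compounds]
    return {c.name: c for c in compounds}


def load_panel_table() -> pd.DataFrame:
    """The transcribed panel tables for all packaged assays as one DataFrame."""
    df = pd.read_csv(
        _data_path("panels.csv"),
        dtype={"population": "string", "citation": "string", "likelihood_label": "string"},
    )
    return df


def _load_assay_config() -> dict:
    with open(_data_path("assays.yaml")) as fh:
        return yaml.safe_load(fh)


def load_assay_definition(assay_name: str, library: dict[str, Compound] | None = None) -> AssayDefinition:
    config = _load_assay_config()
    if assay_name not in config:
        raise KeyError(
            f"unknown assay {assay_name!r}; packaged assays: {', '.join(sorted(config))}"
        )
    spec = config[assay_name]
    library = library if library is not None else load_compound_library()
    target = library[spec["target"]]
    intervals = tuple(
        ReferenceInterval(
            population=iv["population"],
            low=None if iv.get("low") is None else float(iv["low"]),
            high=float(iv["high"]),
        )
        for iv in spec["reference_intervals"]
    )
    return AssayDefinition(
        assay_name=assay_name,
        target_compound=target,
        spike_concentration=float(spec["spike_ng_ml"]),
        reference_intervals=intervals,
    )


def load_fixture_panel(assay_name: str):
    """Return ``(AssayDefinition, [CrossReactivityRecord], [PlasmaRange])``.

    Cross-reactivity values and plasma ranges are the transcribed table rows
    for the named assay; rows sourced from the vendor package insert keep
    that provenance string and are never recomputed.
    """
    # imported here to avoid a circular import at module load
    from .crossreactivity import CrossReactivityRecord, categorize

    assay = load_assay_definition(assay_name)
    table = load_panel_table()
    rows = table[table["assay"] == assay_name]
    if rows.empty:
        raise KeyError(
            f"unknown assay {assay_name!r}; packaged assays: {', '.join(PACKAGED_ASSAYS)}"
        )
    records: list[CrossReactivityRecord] = []
    ranges: list[PlasmaRange] = []
    seen: set[str] = set()
    for _, row in rows.iterrows():
        name = row["compound"]
        if name not in seen:
            seen.add(name)
            cr = float(row["cross_reactivity_pct"])
            records.append(
                CrossReactivityRecord(
                    assay_name=assay_name,
                    compound_name=name,
                    cross_reactivity_pct=cr,
                    category=categorize(cr),
                    provenance=str(row["provenance"]),
                )
            )
        if pd.notna(row["plasma_high_ng_ml"]):
            ranges.append(
                PlasmaRange(
                    compound_name=name,
                    population=str(row["population"]) if pd.notna(row["population"]) else "",
                    low=float(row["plasma_low_ng_ml"]) if pd.notna(row["plasma_low_ng_ml"]) else None,
                    high=float(row["plasma_high_ng_ml"]),
                    citation=str(row["citation"]) if pd.notna(row["citation"]) else "",
                )
            )
    return assay, records, ranges
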