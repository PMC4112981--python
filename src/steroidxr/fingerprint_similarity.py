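"""Structural-key fingerprints and Tanimoto similarity.

The fingerprint is a 166-bit presence vector over a versioned dictionary of
substructure keys (the public MDL/MACCS key set, shipped as a plain-text
asset). Bit *k* is set when key *k*'s pattern matches the standardized
structure at least ``min_count`` times. Similarity between two fingerprints
is the Tanimoto coefficient ``c / (|a| + |b| - c)``, the fraction of set
bits shared.

The dictionary is a swappable asset: different vendors render the public
keys slightly differently, so exact bit parity with any one commercial
implementation is not promised — similarities computed here reproduce
published values to within a few hundredths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .compound_library import Compound

log = logging.getLogger(__name__)

DEFAULT_DICTIONARY = "public-166-v1"
_DICTIONARY_FILES = {"public-166-v1": "keys166_v1.tsv"}

#: engine-evaluated key patterns that SMARTS cannot express directly
_SPECIALS = ("@isotope", "@aromatic_ring", "@fragment")


class FingerprintError(ValueError):
    """Raised for dictionary or fingerprint misuse."""


@dataclass(frozen=True)
class StructuralKey:
    index: int  # 1-based key index
    pattern: str  # SMARTS or an @special token
    min_count: int
    comment: str = ""


class KeyDictionary:
    """A versioned, compiled set of structural keys.

    Parameters
    ----------
    version:
        Dictionary identifier recorded on every fingerprint.
    keys:
        Keys with 1-based dense indices.
    """

    def __init__(self, version: str, keys: Sequence[StructuralKey]):
        indices = [k.index for k in keys]
        if sorted(indices) != list(range(1, len(keys) + 1)):
            raise FingerprintError("key indices must be unique and dense from 1")
        self.version = version
        self.keys = tuple(sorted(keys, key=lambda k: k.index))
        self._queries: list[Chem.Mol | None] = []
        for key in self.keys:
            if key.pattern in _SPECIALS:
                self._queries.append(None)
                continue
            query = Chem.MolFromSmarts(key.pattern)
            if query is None:
                raise FingerprintError(
                    f"key {key.index} pattern does not compile: {key.pattern!r}"
                )
            self._queries.append(query)

    def __len__(self) -> int:
        return len(self.keys)

    @classmethod
    def from_file(cls, path: str | Path, version: str) -> "KeyDictionary":
        keys = []
        for raw in Path(path).read_text().splitlines():
            line = raw.rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FingerprintError(f"malformed dictionary line: {raw!r}")
            comment = fields[3].lstrip("# ").strip() if len(fields) > 3 else ""
            keys.append(
                StructuralKey(
                    index=int(fields[0]),
                    pattern=fields[1],
                    min_count=int(fields[2]),
                    comment=comment,
                )
            )
        return cls(version=version, keys=keys)

    @classmethod
    def load(cls, version: str = DEFAULT_DICTIONARY) -> "KeyDictionary":
        """Load a packaged dictionary by version name."""
        try:
            filename = _DICTIONARY_FILES[version]
        except KeyError:
            raise FingerprintError(
                f"unknown dictionary version {version!r}; packaged: {sorted(_DICTIONARY_FILES)}"
            ) from None
        path = Path(str(resources.files("steroidxr.data").joinpath(filename)))
        return cls.from_file(path, version=version)


@dataclass(frozen=True)
class StructuralKeyFingerprint:
    """Presence bit vector over a key dictionary."""

    dictionary_version: str
    bits: np.ndarray  # uint8 0/1, length == dictionary size

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        if not np.isin(bits, (0, 1)).all():
            raise FingerprintError("fingerprint bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    @property
    def n_set(self) -> int:
        return int(self.bits.sum())

    def on_bits(self) -> list[int]:
        """1-based indices of set keys."""
        return [int(i) + 1 for i in np.flatnonzero(self.bits)]

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, hexstring: str, dictionary_version: str, n_keys: int = 166):
        bits = np.unpackbits(np.frombuffer(bytes.fromhex(hexstring), dtype=np.uint8))[:n_keys]
        return cls(dictionary_version=dictionary_version, bits=bits)


@dataclass(frozen=True)
class SimilarityScore:
    query_name: str
    reference_name: str
    tanimoto: float


def _count_aromatic_rings(mol: Chem.Mol) -> int:
    ri = mol.GetRingInfo()
    count = 0
    for ring in ri.BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            count += 1
    return count


def _match_count(mol: Chem.Mol, key: StructuralKey, query: Chem.Mol | None) -> int:
    if key.pattern == "@isotope":
        return sum(1 for atom in mol.GetAtoms() if atom.GetIsotope() != 0)
    if key.pattern == "@aromatic_ring":
        return _count_aromatic_rings(mol)
    if key.pattern == "@fragment":
        return len(Chem.GetMolFrags(mol))
    return len(mol.GetSubstructMatches(query, uniquify=True))


def compute_fingerprint(compound: Compound, dictionary: KeyDictionary) -> StructuralKeyFingerprint:
    """Fingerprint a standardized compound against a key dictionary.

    Raises
    ------
    FingerprintError
        If the compound is not standardized — stereo or counterion bits
        would make the keys meaningless for 2D similarity.
    """
    if not compound.standardized:
        raise FingerprintError(
            f"{compound.name}: compound must be standardized before fingerprinting"
        )
    mol = compound.structure
    bits = np.zeros(len(dictionary), dtype=np.uint8)
    for pos, (key, query) in enumerate(zip(dictionary.keys, dictionary._queries)):
        if _match_count(mol, key, query) >= key.min_count:
            bits[pos] = 1
    return StructuralKeyFingerprint(dictionary_version=dictionary.version, bits=bits)


def tanimoto(a: StructuralKeyFingerprint, b: StructuralKeyFingerprint) -> float:
    """Tanimoto coefficient ``c / (|a| + |b| - c)`` over set bits.

    Two all-zero fingerprints score 1.0 by convention (logged as degenerate);
    an all-zero against a non-empty fingerprint scores 0.0.
    """
    if a.dictionary_version != b.dictionary_version:
        raise FingerprintError(
            f"dictionary mismatch: {a.dictionary_version!r} vs {b.dictionary_version!r}"
        )
    shared = int(np.bitwise_and(a.bits, b.bits).sum())
    union = a.n_set + b.n_set - shared
    if union == 0:
        log.warning("tanimoto of two empty fingerprints: returning 1.0 by convention")
        return 1.0
    return shared / union


def similarity_panel(
    targets: Sequence[Compound],
    candidates: Sequence[Compound],
    dictionary: KeyDictionary | None = None,
) -> list[SimilarityScore]:
    """Tanimoto similarity of every candidate against every target.

    One score per (candidate, target) pair, stable in input order
    (candidates outer, targets inner). All compounds must be standardized.
    """
    dictionary = dictionary or KeyDictionary.load()
    target_fps = [(t.name, compute_fingerprint(t, dictionary)) for t in targets]
    scores: list[SimilarityScore] = []
    for cand in candidates:
        fp = compute_fingerprint(cand, dictionary)
        for tname, tfp in target_fps:
            scores.append(
                SimilarityScore(query_name=cand.name, reference_name=tname, tanimoto=tanimoto(fp, tfp))
            )
    return scores
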