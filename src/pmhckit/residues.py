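"""Amino-acid code tables and packaged-data access.

Non-canonical residues are handled through a packaged modified-residue map
(e.g. MSE -> MET). A residue that is neither canonical nor mapped raises
:class:`~pmhckit.errors.NonCanonicalResidueError` — modelling it silently
would corrupt the peptide sequence the whole pipeline keys on.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .errors import NonCanonicalResidueError

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
CANONICAL_LETTERS = frozenset(AA1_TO_3)


def data_path(name: str):
    """Path-like handle to a packaged data file."""
    return resources.files("pmhckit.data").joinpath(name)


def load_json_data(name: str) -> dict:
    with resources.files("pmhckit.data").joinpath(name).open() as fh:
        return json.load(fh)


@lru_cache(maxsize=1)
def modified_residue_map() -> dict[str, str]:
    data = load_json_data("modified_residues.json")
    return {k: v for k, v in data.items() if not k.startswith("_")}


def three_to_one(resname: str, *, strict: bool = True) -> str:
    """Map a 3-letter residue code to 1-letter, resolving packaged
    modified-residue parents. ``strict=False`` returns ``X`` instead of
    raising on unknown codes."""
    resname = resname.strip().upper()
    if resname in AA3_TO_1:
        return AA3_TO_1[resname]
    parent = modified_residue_map().get(resname)
    if parent is not None:
        return AA3_TO_1[parent]
    if strict:
        raise NonCanonicalResidueError(
            f"residue {resname!r} is not canonical and has no entry in the "
            "modified-residue map"
        )
    return "X"


def one_to_three(letter: str) -> str:
    letter = letter.upper()
    try:
        return AA1_TO_3[letter]
    except KeyError:
        raise NonCanonicalResidueError(f"unknown 1-letter code {letter!r}") from None
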