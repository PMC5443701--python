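"""Build molecule models from protein / nucleic-acid sequences.

Linear molecules are represented as rigid hollow cylinders at full extension:
polypeptides D = 0.5 nm at 0.38 nm/residue, ssDNA D = 1 nm and dsDNA D = 2 nm
at 0.34 nm per base (pair).  Ionizable side chains, termini and phosphates
are counted from the sequence and assigned pKa/valence from the shipped
table (every entry overridable).
"""

from __future__ import annotations

from Bio import SeqIO

from .constants import (
    CYLINDER_DIAMETERS,
    RISE_PER_BASE,
    RISE_PER_RESIDUE,
    load_pka_table,
)
from .core import IonizableGroup, IonizableGroupSet
from .exceptions import InvalidParameterError
from .models import CylinderModel

__all__ = ["read_fasta", "build_from_sequence", "add_extra_charges"]

_THREE = {
    "D": "ASP", "E": "GLU", "K": "LYS", "C": "CYS", "H": "HIS",
    "R": "ARG", "Y": "TYR",
}
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
_NUCLEIC_ALPHABET = set("ACGTU")


def read_fasta(path) -> str:
    """First record of a FASTA file as an upper-case sequence string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InvalidParameterError(f"no FASTA records in {path}")
    return str(records[0].seq).upper()


def _group_from_entry(name: str, entry: dict, overrides: dict | None) -> IonizableGroup:
    e = dict(entry)
    if overrides and name in overrides:
        e.update(overrides[name])
    return IonizableGroup(
        pka=float(e["pka"]), valence=int(e["valence"]),
        ion_radius=float(e.get("ion_radius", 0.25)), label=name,
    )


def build_from_sequence(
    sequence: str,
    kind: str,
    pka_table: dict | None = None,
    include_termini: bool = True,
    include_cys: bool = True,
    rise: float | None = None,
    diameter: float | None = None,
) -> CylinderModel:
    """Count ionizable groups in a sequence and build the cylinder model.

    ``kind``: "protein" | "ssDNA" | "dsDNA".  For dsDNA the sequence is one
    strand; two phosphates are counted per base pair.  ``pka_table`` entries
    override the shipped defaults per group label.
    """
    sequence = "".join(sequence.split()).upper()
    if not sequence:
        raise InvalidParameterError("empty sequence")
    if kind not in CYLINDER_DIAMETERS:
        raise InvalidParameterError(
            f"kind must be one of {sorted(CYLINDER_DIAMETERS)}, got {kind!r}"
        )
    table = load_pka_table()

    if kind == "protein":
        bad = [i for i, ch in enumerate(sequence) if ch not in _PROTEIN_ALPHABET]
        if bad:
            raise InvalidParameterError(
                f"unknown residue codes at positions {bad[:10]}"
            )
        counts: dict[str, int] = {}
        for ch in sequence:
            name = _THREE.get(ch)
            if name is None or (name == "CYS" and not include_cys):
                continue
            counts[name] = counts.get(name, 0) + 1
        if include_termini:
            counts["NTERM"] = counts.get("NTERM", 0) + 1
            counts["CTERM"] = counts.get("CTERM", 0) + 1
        groups = tuple(
            (_group_from_entry(name, table["protein"][name], pka_table), n)
            for name, n in sorted(counts.items())
        )
        length = len(sequence) * (rise if rise is not None else RISE_PER_RESIDUE)
    else:
        bad = [i for i, ch in enumerate(sequence) if ch not in _NUCLEIC_ALPHABET]
        if bad:
            raise InvalidParameterError(
                f"unknown nucleotide codes at positions {bad[:10]}"
            )
        per_unit = 2 if kind == "dsDNA" else 1
        phosphate = _group_from_entry(
            "PHOSPHATE", table["nucleic"]["PHOSPHATE"], pka_table
        )
        groups = ((phosphate, per_unit * len(sequence)),)
        length = len(sequence) * (rise if rise is not None else RISE_PER_BASE)

    d = diameter if diameter is not None else CYLINDER_DIAMETERS[kind]
    return CylinderModel(
        radius=d / 2.0,
        length=length,
        surface_groups=IonizableGroupSet(groups),
        regulation_enabled=True,
    )


def add_extra_charges(model: CylinderModel, extra) -> CylinderModel:
    """Append extra ionizable groups (e.g. dye moieties) to the inventory.

    ``extra``: iterable of (count, pka, valence) triples.  Effectively
    permanent charges can be encoded with a pKa far from the working pH.
    """
    extra = list(extra)
    if not extra:
        return model
    additions = tuple(
        (IonizableGroup(pka=float(p), valence=int(z), label=f"extra{i}"), float(n))
        for i, (n, p, z) in enumerate(extra)
    )
    from dataclasses import replace

    return replace(
        model, surface_groups=model.surface_groups.with_extra(additions)
    )
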