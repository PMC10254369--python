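"""Molecular geometries and extended-XYZ input/output.

A :class:`Geometry` is an element list plus Cartesian coordinates in Å with
optional reference energy (kJ/mol) and per-atom gradient (kJ/mol/Å).  Surface
toy systems (e.g. the Müller–Brown model) are represented as a single
pseudo-atom whose x/y coordinates are the surface point; the z component is
carried along and ignored by surface potentials.

The extended-XYZ dialect written here stores the per-frame energy under
``energy=`` in the comment line and per-atom forces in three trailing columns
(``forces``, sign convention force = −gradient).  Lattice keys are never
written (all systems are non-periodic).  Electric-dipole entries present in
external records (``dipole=...``) are parsed and discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .constants import element_symbol, symbol_to_z


@dataclass
class Geometry:
    """Element list + Cartesian coordinates with optional reference data."""

    atomic_numbers: tuple[int, ...]
    coordinates: np.ndarray  # (n_atoms, 3), Å
    tag: str = ""
    ref_energy: float | None = None
    ref_gradient: np.ndarray | None = None  # (n_atoms, 3), kJ/mol/Å

    def __post_init__(self) -> None:
        self.atomic_numbers = tuple(int(z) for z in self.atomic_numbers)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atomic_numbers), 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{len(self.atomic_numbers)} atoms"
            )
        if any(z < 1 for z in self.atomic_numbers):
            raise ValueError("atomic numbers must be >= 1")
        if self.ref_gradient is not None:
            self.ref_gradient = np.asarray(self.ref_gradient, dtype=float)
            if self.ref_gradient.shape != self.coordinates.shape:
                raise ValueError("ref_gradient shape must match coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    def with_coordinates(self, coords: np.ndarray) -> "Geometry":
        """Copy with new coordinates; reference data is dropped (it no longer applies)."""
        return Geometry(self.atomic_numbers, np.array(coords, dtype=float), tag=self.tag)

    def copy(self) -> "Geometry":
        g = replace(self)
        g.coordinates = self.coordinates.copy()
        if g.ref_gradient is not None:
            g.ref_gradient = self.ref_gradient.copy()
        return g

    def flat(self) -> np.ndarray:
        return self.coordinates.reshape(-1)


def _format_float(x: float) -> str:
    return repr(float(x))


def _parse_comment(comment: str) -> dict:
    """Parse key=value pairs from an extended-XYZ comment line.

    Values may be bare tokens or double-quoted strings (quoted values may
    contain spaces, as in ``dipole="0.1 0.2 0.3"``).
    """
    out: dict[str, str] = {}
    for m in re.finditer(r'(\S+?)="([^"]*)"|(\S+?)=(\S+)', comment):
        if m.group(1) is not None:
            out[m.group(1)] = m.group(2)
        else:
            out[m.group(3)] = m.group(4)
    return out


def write_xyz_frames(path, geometries: Iterable[Geometry], comments: Sequence[dict] | None = None) -> None:
    """Write geometries as extended-XYZ.

    Per-frame ``energy=`` (from ``ref_energy``) and per-atom force columns
    (from ``ref_gradient``, force = −gradient) are emitted when present.
    Extra comment key/value pairs may be supplied per frame via *comments*.
    """
    geometries = list(geometries)
    with open(path, "w") as fh:
        for i, geom in enumerate(geometries):
            fh.write(f"{geom.n_atoms}\n")
            parts = []
            if geom.ref_energy is not None:
                parts.append(f"energy={_format_float(geom.ref_energy)}")
            props = "species:S:1:pos:R:3"
            if geom.ref_gradient is not None:
                props += ":forces:R:3"
            parts.append(f"Properties={props}")
            if geom.tag:
                parts.append(f'tag="{geom.tag}"')
            if comments is not None:
                for k, v in comments[i].items():
                    sv = str(v)
                    parts.append(f'{k}="{sv}"' if " " in sv else f"{k}={sv}")
            fh.write(" ".join(parts) + "\n")
            for j, z in enumerate(geom.atomic_numbers):
                row = [element_symbol(z)] + [_format_float(c) for c in geom.coordinates[j]]
                if geom.ref_gradient is not None:
                    row += [_format_float(-g) for g in geom.ref_gradient[j]]
                fh.write(" ".join(row) + "\n")


def read_xyz_frames(path) -> list[tuple[Geometry, dict]]:
    """Read extended-XYZ frames; returns (Geometry, comment-fields) pairs.

    Recognized comment keys: ``energy`` (kJ/mol) and a ``forces`` block in the
    Properties declaration.  ``dipole`` entries are parsed but ignored.
    """
    frames: list[tuple[Geometry, dict]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        fields = _parse_comment(lines[i + 1])
        props = fields.get("Properties", "species:S:1:pos:R:3")
        has_forces = "forces" in props
        zs, coords, grads = [], [], []
        for row in lines[i + 2 : i + 2 + n]:
            toks = row.split()
            zs.append(symbol_to_z(toks[0]))
            coords.append([float(t) for t in toks[1:4]])
            if has_forces:
                grads.append([-float(t) for t in toks[4:7]])
        energy = float(fields["energy"]) if "energy" in fields else None
        geom = Geometry(
            tuple(zs),
            np.array(coords),
            tag=fields.get("tag", ""),
            ref_energy=energy,
            ref_gradient=np.array(grads) if has_forces else None,
        )
        frames.append((geom, fields))
        i += 2 + n
    return frames


def surface_point(x: float, y: float) -> Geometry:
    """A 2-D surface point wrapped as a single-pseudo-atom geometry."""
    return Geometry((1,), np.array([[float(x), float(y), 0.0]]))
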