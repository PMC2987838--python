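"""Structure and ensemble I/O.

Reads single- and multi-model PDB files into lightweight ``Structure`` /
``Ensemble`` containers, assigns van der Waals radii and charges, and
resolves atom selections written in a small text grammar.

Parsing is delegated to :mod:`gemmi`; on top of it this module applies a
fixed altloc policy (highest occupancy, ties broken alphabetically) and the
ion-disambiguation rule (HETATM + single-atom residue named NA/CA/MG is a
cation, so an ion "CA" is never confused with an alpha-carbon). Writing uses
a strict-column formatter so that read(write(x)) round-trips coordinates at
PDB precision (three decimals).
"""

from __future__ import annotations

import importlib.resources
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "IonSpecies",
    "Selection",
    "PDBParseError",
    "ION_RESNAMES",
    "load_default_tables",
    "ion_species",
    "read_structure",
    "read_ensemble",
    "assign_properties",
    "write_structure",
    "write_ensemble",
]

ION_RESNAMES = ("NA", "CA", "MG")


class PDBParseError(ValueError):
    """Raised for malformed ATOM/HETATM records (carries the line number)."""


def load_default_tables() -> dict:
    """Load the packaged defaults (radii, charges, ion species, templates)."""
    ref = importlib.resources.files("ionsite.data") / "defaults.toml"
    with ref.open("rb") as fh:
        return tomllib.load(fh)


_TABLES = load_default_tables()
WATER_RESNAMES = frozenset(_TABLES["water"]["resnames"])


@dataclass(frozen=True)
class IonSpecies:
    """A cation species with its first-shell cutoff and maximal CN.

    ``shell_cutoff`` is the outer limit of the first solvation shell in
    angstroms (first minimum of the ion-oxygen radial distribution
    function); ``cn_max`` the maximal coordination number the species
    supports (9 for Ca2+, 6 for Na+ and Mg2+).
    """

    symbol: str
    charge: int
    shell_cutoff: float
    cn_max: int

    def __post_init__(self) -> None:
        if self.charge not in (1, 2):
            raise ValueError(f"unsupported ion charge {self.charge}")
        if not 2.0 < self.shell_cutoff < 4.0:
            raise ValueError(f"shell cutoff {self.shell_cutoff} out of (2, 4) A")


def ion_species(symbol: str) -> IonSpecies:
    """Look up a packaged :class:`IonSpecies` by element symbol (e.g. ``Mg``)."""
    key = symbol.upper()
    try:
        row = _TABLES["ions"][key]
    except KeyError:
        raise KeyError(f"no packaged ion species for {symbol!r}") from None
    return IonSpecies(key.capitalize(), row["charge"], row["shell_cutoff"], row["cn_max"])


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    coords: np.ndarray
    radius: float | None = None
    partial_charge: float = 0.0
    is_water: bool = False
    is_ion: bool = False
    record: str = "ATOM"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} has invalid coordinates")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resid, self.resname)


@dataclass
class Structure:
    """An ordered list of atoms with convenience selection/coordinate views."""

    atoms: list[Atom]
    title: str = ""
    source: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=xyz[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms, self.title, self.source)

    def subset(self, indices: Iterable[int]) -> "Structure":
        idx = list(indices)
        return Structure([self.atoms[i] for i in idx], self.title, self.source)

    def select(self, expression: "Selection | str") -> np.ndarray:
        sel = expression if isinstance(expression, Selection) else Selection(expression)
        return sel.resolve(self)

    def residues(self) -> Iterator[tuple[tuple[str, int, str], list[int]]]:
        """Iterate (residue_key, atom index list) over contiguous residues."""
        current: tuple[str, int, str] | None = None
        members: list[int] = []
        for i, a in enumerate(self.atoms):
            if a.residue_key != current:
                if members:
                    yield current, members  # type: ignore[misc]
                current, members = a.residue_key, []
            members.append(i)
        if members:
            yield current, members  # type: ignore[misc]


@dataclass
class Ensemble:
    """Frames sharing one topology (identical atom count, order and naming)."""

    frames: list[Structure]
    frame_times: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("an ensemble needs at least one frame")
        n0 = len(self.frames[0])
        for k, fr in enumerate(self.frames):
            if len(fr) != n0:
                raise ValueError(
                    f"frame {k} has {len(fr)} atoms, expected {n0} (topology mismatch)"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0])

    @property
    def coords(self) -> np.ndarray:
        return np.stack([fr.coords for fr in self.frames])


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_BARE_KEYWORDS = {"water", "ion", "protein", "all"}
_FIELD_KEYWORDS = {"chain", "resid", "resname", "name", "element"}


@dataclass(frozen=True)
class Selection:
    """A small, deterministic atom-selection grammar.

    Clauses joined with ``and``; each clause is either a bare keyword
    (``water``, ``ion``, ``protein``, ``all``) or ``field values`` where
    field is one of chain / resid / resname / name / element.  ``resid``
    accepts comma-separated numbers and ``a-b`` ranges; other fields accept
    comma-separated literals.  A clause may be negated with a leading
    ``not``.  Resolution returns atom indices in file order.
    """

    expression: str

    def resolve(self, s: Structure) -> np.ndarray:
        mask = np.ones(len(s), dtype=bool)
        expr = self.expression.strip()
        if not expr:
            raise ValueError("empty selection expression")
        for clause in (c.strip() for c in expr.split(" and ")):
            tokens = clause.split()
            if not tokens:
                raise ValueError(f"empty clause in selection {self.expression!r}")
            negate = tokens[0] == "not"
            if negate:
                tokens = tokens[1:]
            if not tokens:
                raise ValueError(f"dangling 'not' in {self.expression!r}")
            key = tokens[0].lower()
            if key in _BARE_KEYWORDS:
                if len(tokens) != 1:
                    raise ValueError(f"keyword {key!r} takes no arguments")
                m = self._keyword_mask(s, key)
            elif key in _FIELD_KEYWORDS:
                if len(tokens) < 2:
                    raise ValueError(f"clause {clause!r} needs values")
                values = " ".join(tokens[1:])
                m = self._field_mask(s, key, values)
            else:
                raise ValueError(f"unknown selection keyword {key!r}")
            mask &= ~m if negate else m
        return np.flatnonzero(mask)

    @staticmethod
    def _keyword_mask(s: Structure, key: str) -> np.ndarray:
        if key == "all":
            return np.ones(len(s), dtype=bool)
        if key == "water":
            return np.array([a.is_water for a in s.atoms])
        if key == "ion":
            return np.array([a.is_ion for a in s.atoms])
        return np.array([not (a.is_water or a.is_ion) for a in s.atoms])

    @staticmethod
    def _field_mask(s: Structure, key: str, values: str) -> np.ndarray:
        items = [v.strip() for v in values.split(",") if v.strip()]
        if key == "resid":
            ok: set[int] = set()
            for item in items:
                if "-" in item[1:]:
                    lo, hi = item.split("-", 1) if not item.startswith("-") else (
                        item[: item.index("-", 1)],
                        item[item.index("-", 1) + 1 :],
                    )
                    ok.update(range(int(lo), int(hi) + 1))
                else:
                    ok.add(int(item))
            return np.array([a.resid in ok for a in s.atoms])
        wanted = {v.upper() for v in items}
        if key == "chain":
            return np.array([a.chain.upper() in wanted for a in s.atoms])
        if key == "resname":
            return np.array([a.resname.upper() in wanted for a in s.atoms])
        if key == "name":
            return np.array([a.name.upper() in wanted for a in s.atoms])
        return np.array([a.element.upper() in wanted for a in s.atoms])


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _precheck_pdb(path: Path) -> None:
    # gemmi tolerates short records; enforce the coordinate-field contract
    # ourselves so malformed lines fail with their line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"line {lineno}: truncated coordinate record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: unparseable coordinates in {line[:30]!r}"
                    ) from None


def _convert_model(model: gemmi.Model, source: str, title: str) -> Structure:
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            resname = res.name.strip().upper()
            is_water = resname in WATER_RESNAMES
            het = res.het_flag == "H"
            is_ion = het and resname in ION_RESNAMES and len(res) == 1
            # altloc policy: keep one atom per name — highest occupancy,
            # ties broken by alphabetical altloc identifier
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                elif (at.occ, -ord(at.altloc or "~")) > (prev.occ, -ord(prev.altloc or "~")):
                    by_name[at.name] = at
            for at in res:
                kept = by_name[at.name]
                if kept is not at:
                    continue
                if is_ion:
                    element = resname.capitalize()
                else:
                    element = "H" if at.element.is_hydrogen else at.element.name
                    if element in ("X", ""):
                        element = at.name.strip()[:1]
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name.strip(),
                        element=element,
                        resname=resname,
                        resid=res.seqid.num,
                        chain=chain.name.strip() or "A",
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_water=is_water,
                        is_ion=is_ion,
                        record="HETATM" if het else "ATOM",
                    )
                )
    return Structure(atoms, title=title, source=source)


def read_structure(path: str | Path, model: int | None = None) -> Structure:
    """Read one model from a PDB file.

    ``model`` is the 1-based MODEL record number; ``None`` takes the first
    model. Altlocs are resolved to the highest-occupancy conformer and
    single-atom NA/CA/MG HETATM residues are flagged as ions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _precheck_pdb(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")
    if model is None:
        gm = st[0]
    else:
        gm = None
        for m in st:
            if m.num == model:
                gm = m
                break
        if gm is None:
            raise ValueError(f"{path}: model {model} not present")
    return _convert_model(gm, source=str(path), title=st.name or path.stem)


def read_ensemble(path: str | Path) -> Ensemble:
    """Read a multi-model PDB as an ensemble (one frame per MODEL block)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _precheck_pdb(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")
    frames = [_convert_model(m, str(path), st.name or path.stem) for m in st]
    n0 = len(frames[0])
    for m, fr in zip(st, frames):
        if len(fr) != n0:
            raise ValueError(
                f"{path}: model {m.num} has {len(fr)} atoms, expected {n0}"
            )
    return Ensemble(frames)


# ---------------------------------------------------------------------------
# Property assignment
# ---------------------------------------------------------------------------


def assign_properties(
    s: Structure,
    radius_set: dict[str, float] | None = None,
    charge_scheme: str = "formal",
) -> Structure:
    """Return a copy with van der Waals radii and partial charges assigned.

    Radii are looked up by element (cations use their ionic radii). The
    ``formal`` scheme puts integer side-chain charges on Asp/Glu (-1, split
    -0.5/-0.5 over the carboxylate oxygens), Lys/Arg (+1) and leaves His and
    the termini neutral; ions carry their species charge. The ``tabulated``
    scheme uses the packaged per-atom partial-charge table instead.
    """
    radii = {k.upper(): float(v) for k, v in (radius_set or _TABLES["radii"]).items()}
    if charge_scheme not in ("formal", "tabulated"):
        raise ValueError(f"unknown charge scheme {charge_scheme!r}")
    formal = _TABLES["formal_charges"]
    tab = _TABLES["tabulated_charges"]
    out: list[Atom] = []
    for a in s.atoms:
        key = a.resname.upper() if a.is_ion else a.element.upper()
        if key not in radii:
            raise KeyError(
                f"no radius for atom {a.serial} {a.name} ({a.resname}{a.resid}, "
                f"element {a.element})"
            )
        q = 0.0
        if a.is_ion:
            q = float(ion_species(a.resname).charge)
        elif charge_scheme == "formal":
            q = float(formal.get(a.resname, {}).get(a.name, 0.0))
        else:
            q = float(tab.get(a.resname, {}).get(a.name, tab["backbone"].get(a.name, 0.0)))
            if a.is_water:
                q = 0.0
        out.append(replace(a, radius=radii[key], partial_charge=q))
    return Structure(out, s.title, s.source)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _format_atom(a: Atom) -> str:
    name = a.name
    # standard PDB alignment: 1-char elements start in column 14
    if len(name) < 4 and len(a.element) == 1:
        name = f" {name}"
    elem = a.element.upper()[:2].rjust(2)
    return (
        f"{a.record:<6}{a.serial % 100000:>5} {name:<4} {a.resname:>3} "
        f"{(a.chain or 'A')[:1]}{a.resid % 10000:>4}    "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {elem}"
    )


def write_structure(s: Structure, path: str | Path) -> None:
    write_ensemble(Ensemble([s]), path)


def write_ensemble(e: Ensemble, path: str | Path) -> None:
    """Write a standard multi-model PDB (strict columns, MODEL/ENDMDL)."""
    path = Path(path)
    lines: list[str] = []
    if e.frames[0].title:
        lines.append(f"TITLE     {e.frames[0].title[:60]}")
    multi = len(e.frames) > 1
    for k, fr in enumerate(e.frames, start=1):
        if multi:
            lines.append(f"MODEL     {k:>4}")
        lines.extend(_format_atom(a) for a in fr.atoms)
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
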