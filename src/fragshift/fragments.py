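"""EE-GMFCC fragment enumeration.

A protein of N residues is decomposed into N−2 one-body fragments (each
residue with its two sequence neighbours as conjugate caps), N−3 concap
fragments (the two-residue overlaps, subtracted to cancel double counting),
and distance-selected two-body pairs with their monomer subtractions.
Severed backbone peptide bonds are capped with hydrogen link atoms placed
along the severed-bond direction.  When electrostatic embedding is on, every
structure atom outside a fragment's residue span enters that fragment's
calculation as a background point charge; the resulting double counting of
charge-charge interactions is tracked in a :class:`CorrectionLedger` by
signed multiplicity counting, so that after subtraction every background
pair interaction is counted exactly once.

For the excitation workflow only fragments containing the chromophore are
enumerated: the three one-body fragments around the chromophore residue m,
the two concaps, the chromophore monomer, and one pair fragment per residue
within the two-body cutoff of m and outside the sequence-exclusion window.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np

from .errors import (
    CappingError,
    ConfigurationError,
    FragshiftError,
    InvalidChromophorePositionError,
    MissingChargeError,
    SizeError,
)
from .structure import Atom, ProteinStructure, min_residue_distance

ONE_BODY = "one_body"
CONCAP = "concap"
PAIR = "pair"
MONOMER = "monomer"


@dataclass(frozen=True)
class GmfccConfig:
    """Knobs of the fragmentation scheme.

    cutoff_2b
        Two-body inclusion threshold (Å) on the minimum inter-residue atom
        distance; comparison is inclusive (≤).
    exclusion_window
        Excitation pairs exclude sequence neighbours j in [m−w, m+w].
    ground_state_min_separation
        Ground-state pairs require j ≥ i + this (default 3; sequence
        neighbours are already covered by one-body fragments).
    cap_bond_lengths
        Link-hydrogen bond lengths (Å), keyed by the atom the hydrogen is
        bonded to: "N" for the hydrogen replacing the upstream carbonyl C,
        "C" for the hydrogen replacing the downstream amide N.
    embedding_enabled
        True → EE-GMFCC (background point charges); False → GMFCC.
    """

    cutoff_2b: float = 4.0
    exclusion_window: int = 2
    ground_state_min_separation: int = 3
    cap_bond_lengths: dict = field(default_factory=lambda: {"N": 1.01, "C": 1.09})
    embedding_enabled: bool = True
    hc_ev_nm: float = 1239.84193
    coulomb_k_ev_A: float = 14.3996

    def __post_init__(self) -> None:
        if self.cutoff_2b <= 0:
            raise ConfigurationError("cutoff_2b must be positive")
        if self.exclusion_window < 1:
            raise ConfigurationError("exclusion_window must be ≥ 1")


@dataclass(frozen=True)
class EmbeddingCharge:
    """A background point charge standing for one structure atom."""

    position: np.ndarray
    charge: float
    source: tuple[int, str]  # (residue index, atom name)

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not np.all(np.isfinite(self.position)) or not np.isfinite(self.charge):
            raise FragshiftError(f"embedding charge {self.source}: non-finite data")


@dataclass
class FragmentSpec:
    """One QM calculation: QM atoms (with caps), embedding charges, a sign."""

    id: str
    kind: str
    span: tuple[int, ...]  # residue indices in the QM region
    center_residues: tuple[int, ...]
    qm_atoms: list[Atom]
    cap_atoms: list[Atom]
    sign: int
    embedding: list[EmbeddingCharge] = field(default_factory=list)

    @property
    def source_keys(self) -> list[tuple[int, str]]:
        """(residue, atom-name) keys of the structure atoms in the QM region."""
        return [(a.residue_index, a.name) for a in self.qm_atoms if a.residue_index is not None]

    def contains_residue(self, index: int) -> bool:
        return index in self.span


@dataclass
class CorrectionLedger:
    """Signed appearance counts of background charge pairs, and their Coulomb sum.

    ``pair_multiplicities`` maps an unordered source-key pair to the signed
    number of fragment energies in which the pair's interaction appears
    (QM–QM or QM–background alike).  The correction energy is the Coulomb sum
    over all structure atom pairs weighted by (net multiplicity − 1):
    subtracting it leaves every pair interaction counted exactly once.
    """

    pair_multiplicities: dict[tuple, int] = field(default_factory=dict)
    correction_energy: float = 0.0


def _pair_key(a: tuple[int, str], b: tuple[int, str]) -> tuple:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# capping


def _contiguous_runs(span: tuple[int, ...]) -> list[tuple[int, int]]:
    runs = []
    ordered = sorted(span)
    start = prev = ordered[0]
    for idx in ordered[1:]:
        if idx == prev + 1:
            prev = idx
            continue
        runs.append((start, prev))
        start = prev = idx
    runs.append((start, prev))
    return runs


def _place_cap(anchor: np.ndarray, removed: np.ndarray, length: float, name: str) -> Atom:
    vec = removed - anchor
    norm = np.linalg.norm(vec)
    if norm == 0:
        raise CappingError("severed-bond atoms coincide")
    return Atom(serial=-1, name=name, element="H", coords=anchor + vec / norm * length, charge=0.0)


def cap_hydrogens(
    span: tuple[int, ...], structure: ProteinStructure, cfg: GmfccConfig
) -> list[Atom]:
    """Hydrogen link atoms for every peptide bond severed at the span boundary.

    For each maximal contiguous run [a..b] of the span: if residue a−1 exists
    its C–N(a) bond is severed and a hydrogen is placed on the N side (bonded
    to N(a), default 1.01 Å); if residue b+1 exists the C(b)–N bond is severed
    and a hydrogen is placed on the C side (bonded to C(b), default 1.09 Å).
    A bond only exists when both backbone partners are present — fully
    non-peptidic toy residues need no caps — but a half-present bond is a
    capping error.
    """
    caps: list[Atom] = []
    n = structure.n_residues
    for start, end in _contiguous_runs(tuple(span)):
        if start > 1:
            prev, this = structure.residue(start - 1), structure.residue(start)
            has_c, has_n = prev.has_atom("C"), this.has_atom("N")
            if has_c != has_n:
                raise CappingError(
                    f"cannot cap bond C({start - 1})–N({start}): backbone atom missing"
                )
            if has_c:
                caps.append(
                    _place_cap(
                        this.atom("N").coords,
                        prev.atom("C").coords,
                        cfg.cap_bond_lengths["N"],
                        f"Hcap_N{start}",
                    )
                )
        if end < n:
            this, nxt = structure.residue(end), structure.residue(end + 1)
            has_c, has_n = this.has_atom("C"), nxt.has_atom("N")
            if has_c != has_n:
                raise CappingError(
                    f"cannot cap bond C({end})–N({end + 1}): backbone atom missing"
                )
            if has_c:
                caps.append(
                    _place_cap(
                        this.atom("C").coords,
                        nxt.atom("N").coords,
                        cfg.cap_bond_lengths["C"],
                        f"Hcap_C{end}",
                    )
                )
    return caps


# ---------------------------------------------------------------------------
# fragment construction


def _make_spec(
    structure: ProteinStructure,
    span: tuple[int, ...],
    kind: str,
    centers: tuple[int, ...],
    sign: int,
    frag_id: str,
    cfg: GmfccConfig,
) -> FragmentSpec:
    span = tuple(sorted(span))
    qm_atoms: list[Atom] = []
    for idx in span:
        for a in structure.residue(idx).atoms:
            qm_atoms.append(
                Atom(a.serial, a.name, a.element, a.coords.copy(), a.charge, a.residue_index)
            )
    caps = cap_hydrogens(span, structure, cfg)
    return FragmentSpec(
        id=frag_id,
        kind=kind,
        span=span,
        center_residues=centers,
        qm_atoms=qm_atoms + caps,
        cap_atoms=caps,
        sign=sign,
    )


def build_embedding(
    spec: FragmentSpec, structure: ProteinStructure, cfg: GmfccConfig
) -> FragmentSpec:
    """Attach background point charges for every structure atom outside the span.

    With ``embedding_enabled`` off (GMFCC) the embedding list is empty.
    """
    if not cfg.embedding_enabled:
        return replace(spec, embedding=[])
    if not structure.has_charges():
        raise MissingChargeError(
            f"fragment {spec.id}: embedding requested but structure has no charges"
        )
    emb = [
        EmbeddingCharge(a.coords.copy(), float(a.charge), (res.index, a.name))
        for res in structure.residues
        if res.index not in spec.span
        for a in res.atoms
    ]
    return replace(spec, embedding=emb)


def _select_pairs_excitation(
    structure: ProteinStructure, m: int, cfg: GmfccConfig
) -> list[int]:
    chromo = structure.residue(m)
    out = []
    for res in structure.residues:
        j = res.index
        if abs(j - m) <= cfg.exclusion_window:
            continue
        if min_residue_distance(chromo, res) <= cfg.cutoff_2b:
            out.append(j)
    return out


def excitation_fragments(
    structure: ProteinStructure, m: int | None = None, cfg: GmfccConfig | None = None
) -> list[FragmentSpec]:
    """Enumerate the chromophore-containing fragments of the excitation assembly.

    Returns the three one-body fragments centred on m−1, m, m+1 (sign +1),
    the two concaps {m−1,m} and {m,m+1} (sign −1), one pair fragment {m,j}
    (sign +1) per residue j within the cutoff and outside the exclusion
    window, and — if any pair was selected — a single chromophore monomer
    {m} (sign −1) referenced by all pair corrections.
    """
    cfg = cfg or GmfccConfig()
    if m is None:
        m = structure.chromophore_index
        if m is None:
            raise ConfigurationError("no chromophore designated and no index given")
    n = structure.n_residues
    if not 3 <= m <= n - 2:
        raise InvalidChromophorePositionError(
            f"chromophore at {m} needs 3 ≤ m ≤ N−2 (N={n}) so all one-body fragments exist"
        )
    specs = [
        _make_spec(structure, (c - 1, c, c + 1), ONE_BODY, (c,), +1, f"1b:{c}", cfg)
        for c in (m - 1, m, m + 1)
    ]
    specs += [
        _make_spec(structure, (i, i + 1), CONCAP, (i, i + 1), -1, f"cc:{i}-{i + 1}", cfg)
        for i in (m - 1, m)
    ]
    pair_js = _select_pairs_excitation(structure, m, cfg)
    for j in pair_js:
        specs.append(
            _make_spec(structure, (m, j), PAIR, (m, j), +1, f"pair:{m}-{j}", cfg)
        )
    if pair_js:
        specs.append(_make_spec(structure, (m,), MONOMER, (m,), -1, f"mono:{m}", cfg))
    if cfg.embedding_enabled:
        specs = [build_embedding(s, structure, cfg) for s in specs]
    return specs


def _select_pairs_ground(
    structure: ProteinStructure, cfg: GmfccConfig
) -> list[tuple[int, int]]:
    out = []
    n = structure.n_residues
    for i in range(1, n + 1):
        for j in range(i + cfg.ground_state_min_separation, n + 1):
            if (
                min_residue_distance(structure.residue(i), structure.residue(j))
                <= cfg.cutoff_2b
            ):
                out.append((i, j))
    return out


def ground_state_fragments(
    structure: ProteinStructure, cfg: GmfccConfig | None = None
) -> tuple[list[FragmentSpec], CorrectionLedger]:
    """Enumerate all ground-state fragments and the double-count ledger.

    N−2 one-body fragments (centres 2..N−1), N−3 concaps, and for every pair
    (i, j) with j ≥ i + min-separation within the cutoff: one pair fragment
    plus monomer subtractions.  Monomer specs are emitted once per residue
    and re-referenced by each pair during assembly and ledger counting.
    """
    cfg = cfg or GmfccConfig()
    n = structure.n_residues
    if n < 5:
        raise SizeError(f"need N ≥ 5 residues to fragment, got {n}")
    specs = [
        _make_spec(structure, (c - 1, c, c + 1), ONE_BODY, (c,), +1, f"1b:{c}", cfg)
        for c in range(2, n)
    ]
    specs += [
        _make_spec(structure, (i, i + 1), CONCAP, (i, i + 1), -1, f"cc:{i}-{i + 1}", cfg)
        for i in range(2, n - 1)
    ]
    pairs = _select_pairs_ground(structure, cfg)
    monomer_ids = sorted({idx for p in pairs for idx in p})
    pair_specs = [
        _make_spec(structure, (i, j), PAIR, (i, j), +1, f"pair:{i}-{j}", cfg) for i, j in pairs
    ]
    mono_specs = {
        idx: _make_spec(structure, (idx,), MONOMER, (idx,), -1, f"mono:{idx}", cfg)
        for idx in monomer_ids
    }
    specs += pair_specs + [mono_specs[i] for i in monomer_ids]
    if cfg.embedding_enabled:
        specs = [build_embedding(s, structure, cfg) for s in specs]
        by_id = {s.id: s for s in specs}
        pair_specs = [by_id[s.id] for s in pair_specs]
        mono_specs = {i: by_id[f"mono:{i}"] for i in monomer_ids}

    ledger = _build_ledger(structure, specs, pair_specs, mono_specs, cfg)
    return specs, ledger


def _count_spec(mult: dict, spec: FragmentSpec, sign: int) -> None:
    qm = spec.source_keys
    emb = [e.source for e in spec.embedding]
    for a, b in combinations(qm, 2):
        mult[_pair_key(a, b)] += sign
    for a in qm:
        for c in emb:
            mult[_pair_key(a, c)] += sign


def _build_ledger(
    structure: ProteinStructure,
    specs: list[FragmentSpec],
    pair_specs: list[FragmentSpec],
    mono_specs: dict[int, FragmentSpec],
    cfg: GmfccConfig,
) -> CorrectionLedger:
    mult: dict[tuple, int] = defaultdict(int)
    for spec in specs:
        if spec.kind in (ONE_BODY, CONCAP):
            _count_spec(mult, spec, spec.sign)
    for pspec in pair_specs:
        _count_spec(mult, pspec, +1)
        i, j = pspec.span
        _count_spec(mult, mono_specs[i], -1)
        _count_spec(mult, mono_specs[j], -1)

    correction = 0.0
    if cfg.embedding_enabled and structure.has_charges():
        atoms = list(structure.iter_atoms())
        keys = [(a.residue_index, a.name) for a in atoms]
        coords = np.array([a.coords for a in atoms])
        charges = np.array([a.charge for a in atoms])
        for ai, bi in combinations(range(len(atoms)), 2):
            weight = mult.get(_pair_key(keys[ai], keys[bi]), 0) - 1
            if weight:
                r = float(np.linalg.norm(coords[ai] - coords[bi]))
                correction += weight * cfg.coulomb_k_ev_A * charges[ai] * charges[bi] / r
    return CorrectionLedger(pair_multiplicities=dict(mult), correction_energy=correction)


# ---------------------------------------------------------------------------
# export for external QM engines


def export_fragments(specs: list[FragmentSpec], outdir: str | Path) -> Path:
    """Write one XYZ file per fragment, a point-charge sidecar, and a manifest.

    The sidecar holds one ``x y z q`` line per embedding charge (Å, e).
    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for spec in specs:
        stem = spec.id.replace(":", "_")
        xyz = outdir / f"{stem}.xyz"
        with xyz.open("w") as fh:
            fh.write(f"{len(spec.qm_atoms)}\n{spec.id}\n")
            for a in spec.qm_atoms:
                fh.write(
                    f"{a.element:<2s} {a.coords[0]:12.6f} {a.coords[1]:12.6f} {a.coords[2]:12.6f}\n"
                )
        chg = outdir / f"{stem}.charges"
        with chg.open("w") as fh:
            for e in spec.embedding:
                fh.write(
                    f"{e.position[0]:12.6f} {e.position[1]:12.6f} {e.position[2]:12.6f} "
                    f"{e.charge:12.8f}\n"
                )
        manifest.append(
            {
                "id": spec.id,
                "kind": spec.kind,
                "sign": spec.sign,
                "span": list(spec.span),
                "xyz": xyz.name,
                "charges": chg.name,
                "n_qm_atoms": len(spec.qm_atoms),
                "n_cap_atoms": len(spec.cap_atoms),
                "n_embedding": len(spec.embedding),
            }
        )
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def specs_from_manifest(path: str | Path) -> list[FragmentSpec]:
    """Rebuild skeleton specs (ids, kinds, spans, signs) from a manifest.

    Geometry is not reloaded; the result is sufficient for energy assembly
    from imported QM results.
    """
    entries = json.loads(Path(path).read_text())
    return [
        FragmentSpec(
            id=e["id"],
            kind=e["kind"],
            span=tuple(e["span"]),
            center_residues=tuple(e["span"]),
            qm_atoms=[],
            cap_atoms=[],
            sign=int(e["sign"]),
        )
        for e in entries
    ]
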