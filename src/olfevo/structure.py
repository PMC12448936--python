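"""Structure-led substitution screening between receptor paralogs.

Given predicted structures of two odorant-receptor paralogs, the screen

1. superposes the models on all confidently predicted residues
   (per-residue pLDDT > 70) with a least-squares Kabsch fit,
2. measures regional C-alpha RMSD per annotated transmembrane helix
   under that single global transform (no per-region re-fitting, so a
   local divergence shows up as elevated regional RMSD),
3. enumerates the amino-acid differences between the paralog sequences,
   and
4. greedily substitutes donor residues into the background sequence,
   re-predicting the structure through a pluggable backend after each
   substitution, until the RMSD of the target region (the S5-S6 helices
   that harbor the ligand-binding pocket) drops to the level of the
   other regions.

The prediction backend is any deterministic callable mapping a protein
sequence to a :class:`StructureModel`; real predictors (e.g. a ColabFold
wrapper) and the synthetic mock backend satisfy the same contract.
Predictions are cached by sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "StructureModel",
    "RegionAnnotation",
    "SubstitutionCandidate",
    "ScreenResult",
    "SubstitutionScreen",
    "read_structure",
    "write_structure",
    "confidence_mask",
    "kabsch_superpose",
    "region_rmsd",
    "diff_positions",
    "run_screen",
]

PLDDT_THRESHOLD = 70.0
DEFAULT_STOP_FLOOR_ANGSTROM = 0.15


@dataclass
class StructureModel:
    """C-alpha trace of one predicted receptor model.

    Residue ids are 1-based and contiguous; ``plddt`` holds the
    per-residue predicted local distance difference test score (0-100),
    stored in the B-factor column on disk as structure predictors do.
    """

    sequence: str
    coords: np.ndarray
    plddt: np.ndarray
    model_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        n = len(self.sequence)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if self.plddt.shape != (n,):
            raise ValueError("one pLDDT value per residue required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any((self.plddt < 0) | (self.plddt > 100)):
            raise ValueError("pLDDT must lie in [0, 100]")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


@dataclass
class RegionAnnotation:
    """Named residue ranges (1-based, inclusive), e.g. helices S1..S7."""

    regions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.regions.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"bad range for region {name!r}: ({lo}, {hi})")

    def mask(self, name: str, n_residues: int) -> np.ndarray:
        lo, hi = self.regions[name]
        if hi > n_residues:
            raise ValueError(f"region {name!r} extends beyond sequence ({n_residues})")
        m = np.zeros(n_residues, dtype=bool)
        m[lo - 1 : hi] = True
        return m

    def union_mask(self, names, n_residues: int) -> np.ndarray:
        m = np.zeros(n_residues, dtype=bool)
        for name in names:
            m |= self.mask(name, n_residues)
        return m

    def names(self) -> list[str]:
        return list(self.regions)


@dataclass(frozen=True)
class SubstitutionCandidate:
    """One donor->background residue substitution, e.g. A181D."""

    position: int
    from_res: str
    to_res: str

    def __post_init__(self) -> None:
        if self.from_res == self.to_res:
            raise ValueError("from and to residues are identical")

    @property
    def label(self) -> str:
        return f"{self.from_res}{self.position}{self.to_res}"

    def apply(self, sequence: str) -> str:
        i = self.position - 1
        if sequence[i] != self.from_res:
            raise ValueError(
                f"sequence has {sequence[i]} at {self.position}, expected {self.from_res}"
            )
        return sequence[:i] + self.to_res + sequence[i + 1 :]


@dataclass
class ScreenResult:
    """Outcome of the greedy substitution screen."""

    accepted: list[SubstitutionCandidate]
    trajectory: list[float]
    converged: bool
    threshold: float
    initial_rmsd: float
    evaluations: list[dict] = field(default_factory=list)
    region_rmsd_initial: dict[str, float] = field(default_factory=dict)
    region_rmsd_final: dict[str, float] = field(default_factory=dict)

    @property
    def final_rmsd(self) -> float:
        return self.trajectory[-1] if self.trajectory else self.initial_rmsd

    def summary(self) -> str:
        lines = [
            "Substitution screen".center(50),
            "=" * 50,
            f"{'initial target-region RMSD:':<32}{self.initial_rmsd:.3f} A",
            f"{'final target-region RMSD:':<32}{self.final_rmsd:.3f} A",
            f"{'stop threshold:':<32}{self.threshold:.3f} A",
            f"{'converged:':<32}{self.converged}",
            f"{'accepted substitutions:':<32}"
            + (" + ".join(c.label for c in self.accepted) or "(none)"),
        ]
        for step, (cand, r) in enumerate(zip(self.accepted, self.trajectory), 1):
            lines.append(f"  round {step}: {cand.label:<8} -> {r:.3f} A")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "accepted": [c.label for c in self.accepted],
            "trajectory": self.trajectory,
            "converged": self.converged,
            "threshold": self.threshold,
            "initial_rmsd": self.initial_rmsd,
            "final_rmsd": self.final_rmsd,
            "region_rmsd_initial": self.region_rmsd_initial,
            "region_rmsd_final": self.region_rmsd_final,
            "evaluations": self.evaluations,
        }


# ---------------------------------------------------------------------------
# PDB I/O (C-alpha records, pLDDT in the B-factor column)
# ---------------------------------------------------------------------------

def write_structure(model: StructureModel, path) -> None:
    """Write a C-alpha-only PDB with pLDDT in the B-factor column."""
    n = model.n_residues
    atoms = struc.AtomArray(n)
    atoms.coord = model.coords
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.array(
        [ProteinSequence.convert_letter_1to3(c) for c in model.sequence]
    )
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.set_annotation("b_factor", model.plddt.astype(float))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_structure(path, model_id: str = "", allow_gaps: bool = False) -> StructureModel:
    """Read a C-alpha trace from a PDB file.

    The B-factor column is interpreted as pLDDT.  Rejects files without
    C-alpha atoms and, unless ``allow_gaps``, non-contiguous residue
    numbering (chain breaks).
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, extra_fields=["b_factor"])
    ca = atoms[atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"{path}: no C-alpha atoms")
    order = np.argsort(ca.res_id, kind="stable")
    ca = ca[order]
    res_ids = ca.res_id
    if np.unique(res_ids).size != res_ids.size:
        raise ValueError(f"{path}: duplicate C-alpha per residue")
    if not allow_gaps and np.any(np.diff(res_ids) != 1):
        raise ValueError(f"{path}: chain break (non-contiguous residue ids)")
    seq = "".join(
        ProteinSequence.convert_letter_3to1(rn.capitalize()) for rn in ca.res_name
    )
    return StructureModel(
        sequence=seq,
        coords=ca.coord.copy(),
        plddt=ca.b_factor.astype(float),
        model_id=model_id or str(path),
    )


# ---------------------------------------------------------------------------
# Superposition and regional RMSD
# ---------------------------------------------------------------------------

def confidence_mask(model: StructureModel, threshold: float = PLDDT_THRESHOLD) -> np.ndarray:
    """Boolean mask of residues with pLDDT strictly above ``threshold``.

    Residues at or below the threshold (typically disordered termini)
    are treated as unreliable and excluded from superposition and RMSD.
    """
    return model.plddt > threshold


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, mask: np.ndarray | None = None
):
    """Optimal rigid superposition of paired C-alpha coordinates.

    Least-squares Kabsch fit of ``mobile`` onto ``reference`` over the
    masked positions.  Returns ``(rotation, translation, rmsd)`` with a
    proper rotation (det = +1); apply as ``mobile @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        mobile_f, reference_f = mobile[mask], reference[mask]
    else:
        mobile_f, reference_f = mobile, reference
    if mobile_f.shape != reference_f.shape or mobile_f.ndim != 2:
        raise ValueError("paired (n, 3) coordinate sets required")
    if mobile_f.shape[0] < 3:
        raise ValueError("need at least 3 paired residues to superpose")

    mu_m = mobile_f.mean(axis=0)
    mu_r = reference_f.mean(axis=0)
    h = (mobile_f - mu_m).T @ (reference_f - mu_r)
    u, s, vt = np.linalg.svd(h)
    # degenerate (e.g. collinear) point sets leave the rotation underdetermined
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate point set: superposition underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_r - rot @ mu_m
    moved = mobile_f @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference_f) ** 2, axis=1))))
    return rot, trans, rmsd


def region_rmsd(
    mobile: StructureModel,
    reference: StructureModel,
    regions: RegionAnnotation,
    alignment_mask: np.ndarray | None = None,
    plddt_threshold: float = PLDDT_THRESHOLD,
):
    """Per-region C-alpha RMSD after one global superposition.

    The superposition is fitted on ``alignment_mask`` (default: residues
    confident in both models) and then held fixed; each region's RMSD is
    measured under that global transform, so a localized divergence is
    not absorbed by a per-region re-fit.  Returns
    ``(region -> RMSD, per-residue deviation array, global RMSD)``; the
    deviation is NaN outside the mask.
    """
    if mobile.n_residues != reference.n_residues:
        raise ValueError("models must share residue numbering")
    n = mobile.n_residues
    if alignment_mask is None:
        alignment_mask = confidence_mask(mobile, plddt_threshold) & confidence_mask(
            reference, plddt_threshold
        )
    rot, trans, global_rmsd = kabsch_superpose(
        mobile.coords, reference.coords, alignment_mask
    )
    moved = mobile.coords @ rot.T + trans
    dev = np.sqrt(np.sum((moved - reference.coords) ** 2, axis=1))
    dev_masked = np.where(alignment_mask, dev, np.nan)
    per_region = {}
    for name in regions.names():
        m = regions.mask(name, n) & alignment_mask
        if not m.any():
            raise ValueError(f"region {name!r} empty after confidence masking")
        per_region[name] = float(np.sqrt(np.mean(dev[m] ** 2)))
    return per_region, dev_masked, global_rmsd


def diff_positions(seq_a: str, seq_b: str) -> list[SubstitutionCandidate]:
    """All positions where two equal-length paralog sequences differ.

    Candidates are labeled background-residue / position / donor-residue
    (substituting ``seq_b``'s residue into ``seq_a``).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences differ in length ({len(seq_a)} vs {len(seq_b)}); align first"
        )
    return [
        SubstitutionCandidate(i + 1, a, b)
        for i, (a, b) in enumerate(zip(seq_a, seq_b))
        if a != b
    ]


# ---------------------------------------------------------------------------
# Greedy substitution screen
# ---------------------------------------------------------------------------

class SubstitutionScreen:
    """Greedy forward-selection screen over paralog sequence differences.

    Parameters
    ----------
    background_seq, donor_seq : paralog protein sequences (equal length);
        donor residues are substituted into the background.
    target_model : structure the mutated predictions are compared to
        (typically the predicted donor-paralog model).
    predictor : callable sequence -> StructureModel, deterministic.
    regions : RegionAnnotation of the transmembrane helices.
    target_regions : names whose union is the divergence region to
        collapse (default S5 + S6).
    stop_threshold : stop once the target-region RMSD is at or below
        this; default ``max(0.15 A, median RMSD of non-target regions)``.
    """

    def __init__(
        self,
        background_seq: str,
        donor_seq: str,
        target_model: StructureModel,
        predictor,
        regions: RegionAnnotation,
        target_regions: tuple[str, ...] = ("S5", "S6"),
        stop_threshold: float | None = None,
        plddt_threshold: float = PLDDT_THRESHOLD,
        max_rounds: int | None = None,
    ):
        self.background_seq = background_seq
        self.donor_seq = donor_seq
        self.target_model = target_model
        self.regions = regions
        self.target_regions = tuple(target_regions)
        self.stop_threshold = stop_threshold
        self.plddt_threshold = plddt_threshold
        self.max_rounds = max_rounds
        self._cache: dict[str, StructureModel] = {}
        self._predictor = predictor

    def predict(self, sequence: str) -> StructureModel:
        if sequence not in self._cache:
            self._cache[sequence] = self._predictor(sequence)
        return self._cache[sequence]

    def _target_rmsd(self, model: StructureModel):
        per_region, dev, _ = region_rmsd(
            model, self.target_model, self.regions, plddt_threshold=self.plddt_threshold
        )
        in_target = self.regions.union_mask(self.target_regions, model.n_residues)
        vals = dev[in_target]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError("target region empty after confidence masking")
        rmsd = float(np.sqrt(np.mean(vals**2)))
        return rmsd, per_region

    def run(self) -> ScreenResult:
        candidates = diff_positions(self.background_seq, self.donor_seq)
        base_model = self.predict(self.background_seq)
        base_rmsd, base_regions = self._target_rmsd(base_model)

        others = [
            v for k, v in base_regions.items() if k not in self.target_regions
        ]
        threshold = (
            self.stop_threshold
            if self.stop_threshold is not None
            else max(DEFAULT_STOP_FLOOR_ANGSTROM, float(np.median(others)) if others else 0.0)
        )

        accepted: list[SubstitutionCandidate] = []
        trajectory: list[float] = []
        evaluations: list[dict] = []
        current_seq = self.background_seq
        current_rmsd = base_rmsd
        remaining = list(candidates)
        converged = current_rmsd <= threshold
        max_rounds = self.max_rounds or len(candidates)

        rounds = 0
        while not converged and remaining and rounds < max_rounds:
            rounds += 1
            best = None
            for cand in remaining:
                seq = cand.apply(current_seq)
                rmsd, _ = self._target_rmsd(self.predict(seq))
                evaluations.append(
                    {"round": rounds, "candidate": cand.label, "s5s6_rmsd": rmsd}
                )
                # ties broken toward the lowest position index
                if best is None or rmsd < best[1] - 1e-12:
                    best = (cand, rmsd)
            cand, rmsd = best
            if rmsd >= current_rmsd:
                break  # no candidate reduces the divergence further
            accepted.append(cand)
            trajectory.append(rmsd)
            current_seq = cand.apply(current_seq)
            current_rmsd = rmsd
            remaining = [c for c in remaining if c.position != cand.position]
            converged = current_rmsd <= threshold

        final_regions = self._target_rmsd(self.predict(current_seq))[1]
        return ScreenResult(
            accepted=accepted,
            trajectory=trajectory,
            converged=converged,
            threshold=float(threshold),
            initial_rmsd=float(base_rmsd),
            evaluations=evaluations,
            region_rmsd_initial={k: float(v) for k, v in base_regions.items()},
            region_rmsd_final={k: float(v) for k, v in final_regions.items()},
        )


def run_screen(
    background_seq: str,
    donor_seq: str,
    target_model: StructureModel,
    predictor,
    regions: RegionAnnotation,
    target_regions: tuple[str, ...] = ("S5", "S6"),
    stop_threshold: float | None = None,
) -> ScreenResult:
    """Functional wrapper around :class:`SubstitutionScreen`."""
    return SubstitutionScreen(
        background_seq,
        donor_seq,
        target_model,
        predictor,
        regions,
        target_regions=target_regions,
        stop_threshold=stop_threshold,
    ).run()
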