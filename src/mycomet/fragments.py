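"""MS2/MS3 fragment annotation by exhaustive subformula neutral-loss search.

Given a precursor ion with an assigned elemental composition, every fragment
m/z is matched against all elementwise subformulas of the precursor ion
composition (fragments are modeled as even-electron cations retaining the
charge proton; the complementary loss is a neutral molecule). Assignments
within an absolute mass tolerance (mDa) are ranked by mass error, and MS3
fragments are assigned relative to their MS2 parent's best composition so
that loss paths accumulate along the tree, mirroring the
``[M + H - A - B]+`` notation used for multistage CID pathways.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .chem import (
    ELECTRON_MASS,
    ElementalFormula,
    IonSpecies,
    monoisotopic_mass,
    rdbe,
)

__all__ = [
    "FragmentObservation",
    "LossAssignment",
    "FragmentNode",
    "FragmentationTree",
    "LossFilter",
    "loss_mass",
    "assign_fragment",
    "build_tree",
]


@dataclass(frozen=True)
class FragmentObservation:
    """A single centroided MSn fragment peak."""

    ms_level: int
    precursor_mz: float
    fragment_mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.ms_level < 2:
            raise ValueError("fragment observations require ms_level >= 2")


@dataclass(frozen=True)
class LossAssignment:
    """One neutral-loss hypothesis for a fragment.

    ``fragment_formula`` is the composition of the fragment *ion* (it keeps
    the charge proton); ``loss_formula`` is the neutral molecule ejected in
    this dissociation step; ``cumulative_losses`` is the loss path from the
    MS1 precursor down to this fragment.
    """

    fragment_formula: ElementalFormula
    loss_formula: ElementalFormula
    theoretical_mz: float
    mass_error_mda: float
    observed_loss_mass: float
    cumulative_losses: tuple[ElementalFormula, ...] = ()


def loss_mass(precursor_mz: float, fragment_mz: float) -> float:
    """Observed neutral-loss mass: precursor m/z minus fragment m/z (singly
    charged ions)."""
    if fragment_mz >= precursor_mz:
        raise ValueError("fragment m/z must be below precursor m/z")
    return precursor_mz - fragment_mz


@dataclass(frozen=True)
class LossFilter:
    """Chemical-plausibility filter applied to candidate neutral losses.

    * hydrogen feasibility: loss H count <= 2*C + N + 3;
    * RDBE window: loss RDBE >= ``min_rdbe`` (default -0.5);
    * even-electron losses only unless ``allow_radical``: an even-electron
      neutral molecule has integer RDBE;
    * unsaturation-density cap: loss RDBE <= heavy_atoms/2 + 1, rejecting
      near-fully-unsaturated compositions (a benzene or adenine loss sits
      exactly at the cap; common small-molecule losses are far below it).

    The empty loss (fragment equal to its precursor) always passes.
    """

    min_rdbe: float = -0.5
    allow_radical: bool = False
    max_unsaturation_density: bool = True

    def accepts(self, loss: ElementalFormula) -> bool:
        if not loss:
            return True
        if loss["H"] > 2 * loss["C"] + loss["N"] + 3:
            return False
        r = rdbe(loss)
        if r < self.min_rdbe:
            return False
        if not self.allow_radical and r != int(r):
            return False
        if self.max_unsaturation_density and r > loss.heavy_atom_count / 2 + 1:
            return False
        return True


def _subformulas(f: ElementalFormula):
    symbols = list(f.counts)
    ranges = [range(f[sym] + 1) for sym in symbols]
    for combo in itertools.product(*ranges):
        yield ElementalFormula(dict(zip(symbols, combo)))


def assign_fragment(
    precursor_ion_formula: ElementalFormula,
    fragment_mz: float,
    tolerance_mda: float = 5.0,
    loss_filter: LossFilter | None = None,
    charge: int = 1,
) -> list[LossAssignment]:
    """Enumerate all subformula assignments of a fragment m/z.

    ``precursor_ion_formula`` is the full ion composition including the
    charge proton (e.g. C10H14N5O4 for protonated adenosine). Every
    elementwise subformula whose singly-protonated-ion mass lies within
    ``tolerance_mda`` of ``fragment_mz`` and whose complementary loss passes
    the plausibility filter is returned, ranked by |mass error| ascending,
    ties broken by smaller loss heavy-atom count then Hill order. An empty
    list (no subformula in tolerance) is a valid outcome, not an error.
    """
    if not precursor_ion_formula:
        raise ValueError("precursor formula must be non-empty")
    if tolerance_mda <= 0:
        raise ValueError("tolerance must be positive")
    loss_filter = loss_filter or LossFilter()
    tol_da = tolerance_mda * 1e-3
    out: list[LossAssignment] = []
    for sub in _subformulas(precursor_ion_formula):
        if not sub:
            continue
        mz = (monoisotopic_mass(sub) - charge * ELECTRON_MASS) / abs(charge)
        err = fragment_mz - mz
        if abs(err) > tol_da:
            continue
        loss = precursor_ion_formula - sub
        if not loss_filter.accepts(loss):
            continue
        out.append(
            LossAssignment(
                fragment_formula=sub,
                loss_formula=loss,
                theoretical_mz=mz,
                mass_error_mda=err * 1e3,
                observed_loss_mass=0.0,
            )
        )
    out.sort(
        key=lambda a: (
            abs(a.mass_error_mda),
            a.loss_formula.heavy_atom_count,
            a.loss_formula.hill(),
        )
    )
    return out


@dataclass
class FragmentNode:
    """A fragment observation together with its ranked assignments.

    ``assignments`` may be empty, in which case the node is explicitly
    unassigned (``assigned`` is False) but retained in the tree.
    """

    observation: FragmentObservation
    assignments: list[LossAssignment] = field(default_factory=list)
    children: list["FragmentNode"] = field(default_factory=list)

    @property
    def assigned(self) -> bool:
        return bool(self.assignments)

    @property
    def best(self) -> LossAssignment | None:
        return self.assignments[0] if self.assignments else None


@dataclass
class FragmentationTree:
    """MS1 -> MS2 -> MS3 annotation tree for one precursor."""

    precursor_mz: float
    precursor_ion: IonSpecies
    ms2_nodes: list[FragmentNode] = field(default_factory=list)

    def all_nodes(self) -> list[FragmentNode]:
        out = []
        for node in self.ms2_nodes:
            out.append(node)
            out.extend(node.children)
        return out


def build_tree(
    precursor_mz: float,
    precursor_formula: ElementalFormula,
    ms2: list[FragmentObservation],
    ms3: dict[float, list[FragmentObservation]] | None = None,
    tolerance_mda: float = 5.0,
    isolation_width_da: float = 1.0,
    loss_filter: LossFilter | None = None,
) -> FragmentationTree:
    """Annotate an MS2 spectrum (and optional MS3 blocks) of one precursor.

    ``precursor_formula`` is the *neutral* molecular formula; the precursor
    ion is its [M+H]+ species. ``ms3`` maps each selected MS2 ion m/z to its
    MS3 fragment list; the selected m/z must match an observed MS2 fragment
    within ``isolation_width_da`` (the ion-trap isolation window, default
    1 Da). MS3 fragments are assigned relative to the matched MS2 node's
    best composition and their ``cumulative_losses`` extend the parent's
    loss path. Unassignable fragments are kept with empty assignment lists.
    """
    ion = IonSpecies(precursor_formula, protons_added=1, charge=1)
    ion_comp = ion.composition
    tree = FragmentationTree(precursor_mz=precursor_mz, precursor_ion=ion)
    for obs in sorted(ms2, key=lambda o: -o.intensity):
        assigns = assign_fragment(ion_comp, obs.fragment_mz, tolerance_mda, loss_filter)
        assigns = [
            _with_path(a, (), precursor_mz, obs.fragment_mz) for a in assigns
        ]
        tree.ms2_nodes.append(FragmentNode(obs, assigns))
    for sel_mz, fragments in (ms3 or {}).items():
        parent = _match_node(tree.ms2_nodes, sel_mz, isolation_width_da)
        if parent is None:
            raise ValueError(
                f"MS3 precursor m/z {sel_mz} matches no MS2 fragment within "
                f"{isolation_width_da} Da"
            )
        if parent.best is None:
            for obs in fragments:
                parent.children.append(FragmentNode(obs, []))
            continue
        parent_comp = parent.best.fragment_formula
        parent_path = parent.best.cumulative_losses
        for obs in sorted(fragments, key=lambda o: -o.intensity):
            assigns = assign_fragment(
                parent_comp, obs.fragment_mz, tolerance_mda, loss_filter
            )
            assigns = [
                _with_path(a, parent_path, parent.observation.fragment_mz, obs.fragment_mz)
                for a in assigns
            ]
            parent.children.append(FragmentNode(obs, assigns))
    return tree


def _with_path(
    a: LossAssignment,
    parent_path: tuple[ElementalFormula, ...],
    parent_mz: float,
    frag_mz: float,
) -> LossAssignment:
    path = parent_path + ((a.loss_formula,) if a.loss_formula else ())
    return LossAssignment(
        fragment_formula=a.fragment_formula,
        loss_formula=a.loss_formula,
        theoretical_mz=a.theoretical_mz,
        mass_error_mda=a.mass_error_mda,
        observed_loss_mass=parent_mz - frag_mz if frag_mz < parent_mz else 0.0,
        cumulative_losses=path,
    )


def _match_node(
    nodes: list[FragmentNode], mz: float, width: float
) -> FragmentNode | None:
    best, best_d = None, None
    for node in nodes:
        d = abs(node.observation.fragment_mz - mz)
        if d <= width and (best_d is None or d < best_d):
            best, best_d = node, d
    return best
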