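"""Model selection, ranking, RMSD, and success metrics.

The selection convention: from all models of one docking run, keep the
``n_total_cut`` (default 100 of 1000) lowest by total score, then sort that
subset ascending by ligand interface score; a model's 1-based position in
the sorted list is its rank.  A run *succeeds* when the top-ranked model has
ligand RMSD strictly under 2.0 A.

Ligand RMSD is computed over name-matched heavy-atom pairs with no
superposition (the docking frame is shared); water RMSD is oxygen-only with
correspondence chosen by minimum-cost assignment, since waters are
interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .structure import LigandModel, WaterdockError, WaterSet

SUCCESS_RMSD = 2.0  # A


@dataclass
class ModelRecord:
    """Per-model scores and accuracy."""

    model_id: int
    total_score: float
    interface_ligand: float
    interface_water: float = 0.0
    ligand_rmsd: float = float("nan")
    water_rmsd: float | None = None
    rank: int | None = None


@dataclass
class RunComparison:
    """Model-quality changes between two runs over the same inputs."""

    pairs: list[tuple[float, float]]  # (rmsd_a, rmsd_b) per input
    n_improved: int
    n_worsened: int
    n_improved_significant: int  # |delta| > 1 A
    n_worsened_significant: int


def ligand_rmsd(model: LigandModel, reference: LigandModel) -> float:
    """Heavy-atom RMSD over name-matched pairs, no superposition."""
    ref_map = {
        reference.names[i]: i
        for i in range(len(reference))
        if not reference.is_hydrogen[i]
    }
    model_names = [
        model.names[i] for i in range(len(model)) if not model.is_hydrogen[i]
    ]
    missing = sorted(set(model_names) ^ set(ref_map))
    if missing:
        raise WaterdockError(f"ligand atom name mismatch: {missing}")
    sq = 0.0
    n = 0
    for i in range(len(model)):
        if model.is_hydrogen[i]:
            continue
        j = ref_map[model.names[i]]
        sq += float(np.sum((model.coords[i] - reference.coords[j]) ** 2))
        n += 1
    return float(np.sqrt(sq / n))


def water_rmsd(model: WaterSet, reference: WaterSet) -> float:
    """Oxygen-only RMSD under the optimal water-to-water assignment."""
    if len(model) != len(reference):
        raise WaterdockError(
            f"water count mismatch: {len(model)} vs {len(reference)}"
        )
    if len(model) == 0:
        return 0.0
    d2 = cdist(model.oxygens, reference.oxygens) ** 2
    rows, cols = linear_sum_assignment(d2)
    return float(np.sqrt(d2[rows, cols].mean()))


def select_and_rank(
    records: list[ModelRecord], n_total_cut: int = 100
) -> list[ModelRecord]:
    """Keep the ``n_total_cut`` lowest-total-score models, sort by ligand
    interface score, and assign 1-based ranks (ties: total score, then id)."""
    if not records:
        raise WaterdockError("no model records")
    stage1 = sorted(records, key=lambda r: (r.total_score, r.model_id))[:n_total_cut]
    ranked = sorted(
        stage1, key=lambda r: (r.interface_ligand, r.total_score, r.model_id)
    )
    out = []
    for pos, r in enumerate(ranked, start=1):
        rr = ModelRecord(**{**r.__dict__})
        rr.rank = pos
        out.append(rr)
    return out


def success_metrics(
    ranked: list[ModelRecord], threshold: float = SUCCESS_RMSD
) -> dict:
    """Top-1 success flag and rank of the first sub-threshold model (None if
    none was sampled)."""
    top1 = bool(ranked) and ranked[0].ligand_rmsd < threshold
    rank_first = None
    for r in ranked:
        if r.ligand_rmsd < threshold:
            rank_first = r.rank
            break
    return {"top1_success": top1, "rank_first_under": rank_first}


def compare_runs(
    a: dict[str, float], b: dict[str, float], significant: float = 1.0
) -> RunComparison:
    """Compare per-input top-model RMSDs between two runs.

    ``a`` and ``b`` map input identifiers to the top-ranked model's RMSD.
    Improved means strictly lower in ``b``; the significant tallies use
    ``|delta| > significant`` (strict).
    """
    if set(a) != set(b):
        raise WaterdockError("runs cover different input sets")
    pairs = [(a[k], b[k]) for k in sorted(a)]
    n_imp = sum(1 for x, y in pairs if y < x)
    n_wor = sum(1 for x, y in pairs if y > x)
    n_imp_sig = sum(1 for x, y in pairs if x - y > significant)
    n_wor_sig = sum(1 for x, y in pairs if y - x > significant)
    return RunComparison(pairs, n_imp, n_wor, n_imp_sig, n_wor_sig)
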