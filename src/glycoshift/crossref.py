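"""Cross-reference decreased glycosites against total-proteome evidence.

A drop in a glycosite's signal can mean the site lost its glycan (occupancy
loss) or the whole protein became less abundant. The discriminating evidence
lives in the total-proteome experiment: there, a peptide spanning the site is
only detectable when the site is *unoccupied*. A glycosite that decreased (or
vanished from mutants) whose unmodified counterpart appears in several mutant
samples but never in controls was therefore not glycosylated in the mutant —
the strongest possible label-free evidence of an occupancy loss.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .core_io import CONTROL, MUTANT, QuantMatrix, validate_design
from .differential import DECREASED, EXCLUSIVE_CONTROL

UNOCCUPIED_IN_MUTANT = "unoccupied_in_mutant"
OCCUPANCY_REDUCED_UNCONFIRMED = "occupancy_reduced_unconfirmed"
PROTEIN_LEVEL_CHANGE = "protein_level_change"
UNCHANGED_CALL = "unchanged"

CALLS = (
    UNOCCUPIED_IN_MUTANT,
    OCCUPANCY_REDUCED_UNCONFIRMED,
    PROTEIN_LEVEL_CHANGE,
    UNCHANGED_CALL,
)


def crossref_occupancy(
    glyco_results: pd.DataFrame,
    unmodified_matrix: QuantMatrix,
    protein_results: pd.DataFrame,
    k: int = 3,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify each glycosite result by the fate of its unmodified counterpart.

    For a glycosite with status ``decreased`` or ``exclusive_control``:

    * ``unoccupied_in_mutant`` — its unmodified peptide is detected in >= *k*
      mutant samples and zero control samples;
    * ``protein_level_change`` — the rule above fails and the parent protein
      itself is called decreased in the total proteome (the glyco drop is
      explained by abundance, a disambiguation this pipeline adds);
    * ``occupancy_reduced_unconfirmed`` — otherwise (the counterpart peptide
      was never seen, which label-free MS cannot distinguish from absence).

    All other glycosites pass through as ``unchanged``. Counterparts are
    matched purely by site key — the glycosite and unmodified tables must use
    the same ``protein:position`` feature ids.
    """
    if unmodified_matrix.feature_kind != "unmodified_peptide":
        raise ValueError("counterpart matrix must hold unmodified peptides")
    validate_design(unmodified_matrix.design)
    genotypes = {s.genotype for s in unmodified_matrix.design}
    if genotypes != {CONTROL, MUTANT}:
        raise ValueError("counterpart matrix design must contain both genotypes")

    n_ctrl = unmodified_matrix.n_detected(CONTROL)
    n_mut = unmodified_matrix.n_detected(MUTANT)
    protein_status = protein_results.set_index("feature_id")["status"]

    calls = []
    for row in glyco_results.itertuples(index=False):
        feature = str(row.feature_id)
        counterpart_ctrl = int(n_ctrl.get(feature, 0))
        counterpart_mut = int(n_mut.get(feature, 0))
        if row.status in (DECREASED, EXCLUSIVE_CONTROL):
            protein_id = feature.rpartition(":")[0]
            if counterpart_ctrl == 0 and counterpart_mut >= k:
                call = UNOCCUPIED_IN_MUTANT
            elif protein_status.get(protein_id) == DECREASED:
                call = PROTEIN_LEVEL_CHANGE
            else:
                call = OCCUPANCY_REDUCED_UNCONFIRMED
        else:
            call = UNCHANGED_CALL
        calls.append(
            {
                "feature_id": feature,
                "glyco_status": row.status,
                "counterpart_detected_control": counterpart_ctrl,
                "counterpart_detected_mutant": counterpart_mut,
                "call": call,
            }
        )
    result = pd.DataFrame(
        calls,
        columns=[
            "feature_id",
            "glyco_status",
            "counterpart_detected_control",
            "counterpart_detected_mutant",
            "call",
        ],
    )
    summary = dict(Counter(result["call"])) if len(result) else {}
    for name in CALLS:
        summary.setdefault(name, 0)
    return result, summary
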