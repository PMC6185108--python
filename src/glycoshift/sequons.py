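"""Sequon scanning, site classification and the reference glycoproteome.

N-glycans are attached co-translationally to Asn residues inside the acceptor
sequon Asn-X-Ser/Thr with X != Pro. The +2 residue splits canonical sequons
into the efficient NxT and the less efficient NxS variant, and an aromatic
residue (Phe, Tyr, His or Trp) at position -2 further raises transfer
efficiency. Detected sites that do not match the canonical rule are kept as
``non_canonical`` — such sequons recur among newly identified sites.

The *reference glycoproteome* is evidence-based: a site enters it when its
deglycosylated peptide was detected in at least ``min_control_detections``
control samples. Per-protein *multiplicity* (the number of glycosylation
sites, the central covariate of this pipeline) is counted on the reference,
while ``scanned_multiplicity`` counts canonical sequons found purely by
sequence scanning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import ProteinRecord, QuantMatrix, SiteKey, ParseError, proteins_by_id

#: aromatic residues for the -2 context feature
AROMATIC = frozenset("FYHW")

NXT = "NxT"
NXS = "NxS"
NON_CANONICAL = "non_canonical"
SEQUON_CLASSES = (NXT, NXS, NON_CANONICAL)

SCANNED_ONLY = "scanned_only"
REFERENCE = "reference"
NOVEL = "novel"

#: canonical sequon, overlap-tolerant (lookahead), Asn at match start
_SEQUON_RE = re.compile(r"(?=N[^P][ST])")

#: residues reported on each side of the Asn in the stored context window
CONTEXT_FLANK = 5
CONTEXT_PAD = "-"


@dataclass(frozen=True)
class GlycoSite:
    """One Asn site on a protein with its sequence context and evidence tag."""

    key: SiteKey
    sequon: str  # residues at 0,+1,+2 (may be shorter near the C-terminus)
    sequon_class: str
    minus2_residue: str | None  # None when the site is too close to the N-terminus
    minus2_aromatic: bool | None
    context: str = ""  # 11-mer, Asn centred, '-'-padded
    evidence: str = SCANNED_ONLY

    @property
    def protein_id(self) -> str:
        return self.key.protein_id

    @property
    def position(self) -> int:
        return self.key.position

    @property
    def plus2_residue(self) -> str | None:
        return self.sequon[2] if len(self.sequon) >= 3 else None


def classify_site(protein: ProteinRecord, key: SiteKey) -> GlycoSite:
    """Classify the sequon and -2 context of the Asn at ``key.position``.

    Raises if the residue there is not Asn — that signals a mismatch between
    the evidence table and the sequence database.
    """
    seq = protein.sequence
    pos = key.position
    if key.protein_id != protein.protein_id:
        raise ParseError(f"site {key} does not belong to protein {protein.protein_id}")
    if not 1 <= pos <= len(seq):
        raise ParseError(f"site {key}: position outside protein (length {len(seq)})")
    if seq[pos - 1] != "N":
        raise ParseError(
            f"site {key}: residue at position {pos} is {seq[pos - 1]!r}, not N"
        )
    sequon = seq[pos - 1 : pos + 2]
    if len(sequon) == 3 and sequon[1] != "P" and sequon[2] in "ST":
        sequon_class = NXT if sequon[2] == "T" else NXS
    else:
        sequon_class = NON_CANONICAL
    if pos >= 3:
        minus2: str | None = seq[pos - 3]
        minus2_aromatic: bool | None = minus2 in AROMATIC
    else:
        minus2 = None
        minus2_aromatic = None
    lo = pos - 1 - CONTEXT_FLANK
    hi = pos + CONTEXT_FLANK
    window = seq[max(lo, 0) : hi]
    context = CONTEXT_PAD * max(-lo, 0) + window + CONTEXT_PAD * max(hi - len(seq), 0)
    return GlycoSite(key, sequon, sequon_class, minus2, minus2_aromatic, context)


def scan_sequons(protein: ProteinRecord) -> list[GlycoSite]:
    """All canonical sequons (N-X-S/T, X != Pro) in a protein, overlaps allowed.

    Positions are 1-based; an Asn whose +1/+2 window runs past the C-terminus
    is not reported.
    """
    return [
        classify_site(protein, SiteKey(protein.protein_id, m.start() + 1))
        for m in _SEQUON_RE.finditer(protein.sequence)
    ]


def build_reference_glycoproteome(
    site_matrix: QuantMatrix,
    proteins: Iterable[ProteinRecord] | Mapping[str, ProteinRecord],
    min_control_detections: int = 2,
) -> list[GlycoSite]:
    """Evidence-based site catalogue: detected in >= *min_control_detections*
    control samples.

    Only control detections count — a site seen solely in mutants does not
    enter the reference. Every included site is classified against its
    protein sequence and tagged ``reference``.
    """
    lookup = proteins if isinstance(proteins, Mapping) else proteins_by_id(proteins)
    n_ctrl = site_matrix.n_detected("control")
    out: list[GlycoSite] = []
    for feature_id, count in n_ctrl.items():
        if count < min_control_detections:
            continue
        key = SiteKey.parse(str(feature_id))
        protein = lookup.get(key.protein_id)
        if protein is None:
            raise ParseError(f"feature {feature_id!r}: unknown protein {key.protein_id!r}")
        out.append(replace(classify_site(protein, key), evidence=REFERENCE))
    return out


@dataclass(frozen=True)
class NoveltySummary:
    n_reference: int
    n_novel: int
    novel_fraction: float
    non_canonical_novel_fraction: float  # among novel sites


def call_novel_sites(
    reference: Sequence[GlycoSite],
    known_site_lists: Iterable[set[SiteKey]],
) -> tuple[list[GlycoSite], NoveltySummary]:
    """Tag reference sites absent from every known-site list as ``novel``."""
    known: set[SiteKey] = set()
    for lst in known_site_lists:
        known |= lst
    sites = [
        replace(s, evidence=NOVEL) if s.key not in known else s for s in reference
    ]
    novel = [s for s in sites if s.evidence == NOVEL]
    n_ref = len(reference)
    n_novel = len(novel)
    nc_frac = (
        sum(s.sequon_class == NON_CANONICAL for s in novel) / n_novel if n_novel else 0.0
    )
    summary = NoveltySummary(
        n_reference=n_ref,
        n_novel=n_novel,
        novel_fraction=n_novel / n_ref if n_ref else 0.0,
        non_canonical_novel_fraction=nc_frac,
    )
    return sites, summary


def multiplicity_profiles(
    reference: Sequence[GlycoSite],
    proteins: Iterable[ProteinRecord] | Mapping[str, ProteinRecord],
) -> pd.DataFrame:
    """Per-protein site counts.

    Returns a DataFrame indexed by protein_id with columns ``multiplicity``
    (distinct reference-site positions; 0 marks a non-glycoprotein for
    downstream enrichment) and ``scanned_multiplicity`` (canonical sequons
    found by scanning the sequence).
    """
    lookup = proteins if isinstance(proteins, Mapping) else proteins_by_id(proteins)
    positions: dict[str, set[int]] = {pid: set() for pid in lookup}
    for site in reference:
        if site.protein_id not in positions:
            raise ParseError(f"reference site {site.key} has no protein record")
        positions[site.protein_id].add(site.position)
    rows = {
        pid: (len(positions[pid]), len(scan_sequons(rec)))
        for pid, rec in lookup.items()
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["multiplicity", "scanned_multiplicity"]
    )
    df.index.name = "protein_id"
    return df.sort_index()


def sites_table(sites: Sequence[GlycoSite]) -> pd.DataFrame:
    """Flatten GlycoSites into a writable table (round-trips via sites_from_table)."""
    return pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in sites],
            "position": [s.position for s in sites],
            "sequon": [s.sequon for s in sites],
            "sequon_class": [s.sequon_class for s in sites],
            "minus2_residue": [s.minus2_residue for s in sites],
            "minus2_aromatic": [s.minus2_aromatic for s in sites],
            "context": [s.context for s in sites],
            "evidence": [s.evidence for s in sites],
        }
    )


def sites_from_table(df: pd.DataFrame) -> list[GlycoSite]:
    out = []
    for row in df.itertuples(index=False):
        minus2 = None if pd.isna(row.minus2_residue) else str(row.minus2_residue)
        aromatic = None if pd.isna(row.minus2_aromatic) else bool(row.minus2_aromatic)
        out.append(
            GlycoSite(
                SiteKey(str(row.protein_id), int(row.position)),
                str(row.sequon),
                str(row.sequon_class),
                minus2,
                aromatic,
                str(row.context),
                str(row.evidence),
            )
        )
    return out
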