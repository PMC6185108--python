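"""Scan protein sequences for N-glycosylation sequons and classify their context.

Builds two small proteins, finds every canonical sequon (N-X-S/T, X != Pro,
overlaps allowed), and classifies one extra non-canonical site. Each line
prints the 1-based Asn position, the sequon, its class (NxT / NxS /
non_canonical) and the -2 residue with its aromaticity — the features that
determine how efficiently the oligosaccharyltransferase fills the site.
"""

from glycoshift import ProteinRecord, SiteKey, classify_site, scan_sequons

proteins = [
    ProteinRecord("DEMO1", "MFANGSAQNNTSWNPTK"),  # aromatic -2, overlap, blocked NPT
    ProteinRecord("DEMO2", "MNGTACDNVSGG"),
]

for protein in proteins:
    print(f"{protein.protein_id} ({protein.sequence})")
    for site in scan_sequons(protein):
        print(
            f"  position {site.position:>2}  sequon {site.sequon}  class {site.sequon_class:<13}"
            f"  -2 residue {site.minus2_residue or 'n/a'}"
            f"  aromatic={site.minus2_aromatic}"
        )

# the scanner skips the proline-blocked NPT, but a detected site there can
# still be classified on request: it comes back non-canonical
site = classify_site(proteins[0], SiteKey("DEMO1", 14))
print(f"\nDEMO1 position 14: sequon {site.sequon} -> {site.sequon_class}")
print("(non-canonical sequons recur among newly identified glycosites)")
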