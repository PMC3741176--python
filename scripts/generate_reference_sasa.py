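"""Regenerate the side-chain reference-maximum SASA table.

For each amino acid X, builds an extended Gly-X-Gly tripeptide (CCD
ideal-geometry side chains on an idealized extended backbone), computes the
central residue's side-chain SASA with the package's own Shrake-Rupley
parameters (960-point golden lattice, Bondi radii, 1.4 A probe), and prints
the table to paste into ``psychrotryp.constants.MAX_SIDECHAIN_SASA``.
Glycine's entry is the CA-proxy value from Gly-Gly-Gly.
"""

from psychrotryp.constants import THREE_TO_ONE
from psychrotryp.structure import relative_side_chain_exposure
from psychrotryp.synthetic import build_extended_peptide


def main() -> None:
    table = {}
    for one in sorted({v for v in THREE_TO_ONE.values()}):
        st = build_extended_peptide(f"G{one}G")
        profile = relative_side_chain_exposure(st, reference={one: 1.0, "G": 1.0})
        central = next(r for r in profile if r.residue_number == 2)
        table[one] = round(central.sidechain_sasa, 1)
    for one, val in sorted(table.items()):
        print(f'    "{one}": {val},')


if __name__ == "__main__":
    main()
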