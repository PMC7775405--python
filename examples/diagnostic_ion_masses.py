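"""Print the diagnostic ion reference table used by the glycopeptide validator.

The GlcNAc oxonium ladder and the Neu5Ac reporter pair are the low-mass MS2
ions that distinguish genuine glycopeptide spectra from everything else; the
two negative-mode values are the precursor/fragment pair used for CMP-Neu5Ac.
"""

from glycoprofiler.chem import (
    CMP, CMP_NEU5AC, ElementalComposition, IonSpec, ion_mz, oxonium_mz,
)

rows = [
    ("[GlcNAc]+", oxonium_mz(["HexNAc"])),
    ("[GlcNAc - H2O]+", oxonium_mz(["HexNAc"], water_losses=1)),
    ("[GlcNAc - 2H2O]+", oxonium_mz(["HexNAc"], water_losses=2)),
    ("[GlcNAc - C2H4O2]+", oxonium_mz(["HexNAc"], neutral_loss=ElementalComposition(C=2, H=4, O=2))),
    ("[GlcNAc - CH6O3]+", oxonium_mz(["HexNAc"], neutral_loss=ElementalComposition(C=1, H=6, O=3))),
    ("[GlcNAc - C2H6O3]+", oxonium_mz(["HexNAc"], neutral_loss=ElementalComposition(C=2, H=6, O=3))),
    ("[GlcNAcHex]+", oxonium_mz(["HexNAc", "Hex"])),
    ("[GlcNAcHex2]+", oxonium_mz(["HexNAc", "Hex", "Hex"])),
    ("[Neu5Ac]+", oxonium_mz(["Neu5Ac"])),
    ("[Neu5Ac - H2O]+", oxonium_mz(["Neu5Ac"], water_losses=1)),
    ("[CMP-Neu5Ac - H]-", ion_mz(IonSpec.from_composition(CMP_NEU5AC, 1, "negative"))),
    ("[CMP - H]-", ion_mz(IonSpec.from_composition(CMP, 1, "negative"))),
]
print(f"{'ion':24s} m/z")
for name, mz in rows:
    print(f"{name:24s} {mz:9.3f}")
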