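# Construct topology definitions: ordered segments of stickers (one lattice
# bead each) and linkers (amino-acid counts, converted to spacer beads by the
# spacer scaling factor, default 1/6).
#
# Linker amino-acid counts are editable approximations of the inter-sticker
# segments of SLP65 residues 1-330 and CIN85 residues 1-333 (each PRM spans
# 6 residues, each SH3 domain collapses to a single sticker bead).  Replace
# this file to use exact per-construct linker lengths.

"SLP65_1-330":
  segments:
    - {linker: 40}
    - {sticker: PRM1}
    - {linker: 30}
    - {sticker: PRM2}
    - {linker: 40}
    - {sticker: PRM3}
    - {linker: 104}
    - {sticker: PRM4}
    - {linker: 30}
    - {sticker: PRM5}
    - {linker: 20}
    - {sticker: PRM6}
    - {linker: 30}

"SLP65-3xPRM4":
  # strong-binding variant: PRM5 and PRM6 replaced by PRM4
  segments:
    - {linker: 40}
    - {sticker: PRM1}
    - {linker: 30}
    - {sticker: PRM2}
    - {linker: 40}
    - {sticker: PRM3}
    - {linker: 104}
    - {sticker: PRM4}
    - {linker: 30}
    - {sticker: PRM4}
    - {linker: 20}
    - {sticker: PRM4}
    - {linker: 30}

"SLP65-R247A":
  # weak-binding variant: the R247A mutation deactivates PRM4; the bead
  # stays (geometry unchanged) but is binding-inert
  segments:
    - {linker: 40}
    - {sticker: PRM1}
    - {linker: 30}
    - {sticker: PRM2}
    - {linker: 40}
    - {sticker: PRM3}
    - {linker: 104}
    - {sticker: PRM4, inert: true}
    - {linker: 30}
    - {sticker: PRM5}
    - {linker: 20}
    - {sticker: PRM6}
    - {linker: 30}

"CIN85-ABC":
  segments:
    - {sticker: SH3A}
    - {linker: 38}
    - {sticker: SH3B}
    - {linker: 77}
    - {sticker: SH3C}
    - {linker: 42}

"CIN85-AB":
  # weak-binding bivalent variant: SH3A and SH3B only
  segments:
    - {sticker: SH3A}
    - {linker: 38}
    - {sticker: SH3B}
    - {linker: 5}

"CIN85-BBB":
  # strong-binding variant: SH3A and SH3C each replaced by SH3B
  segments:
    - {sticker: SH3B}
    - {linker: 38}
    - {sticker: SH3B}
    - {linker: 77}
    - {sticker: SH3B}
    - {linker: 42}

"CIN85-ABC-DM":
  # R227A/R229A double mutant deactivates CIN85's own PRM1; since the
  # intramolecular SH3C-PRM1 bond is not part of the lattice model, the
  # simulated topology is identical to CIN85-ABC
  segments:
    - {sticker: SH3A}
    - {linker: 38}
    - {sticker: SH3B}
    - {linker: 77}
    - {sticker: SH3C}
    - {linker: 42}
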