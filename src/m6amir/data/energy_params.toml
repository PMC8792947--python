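# Reduced nearest-neighbor RNA energy parameters (kcal/mol, 37 C).
#
# Stacks follow the Turner-style convention stack("XY") where X is the outer
# pair (top-strand nucleotide first) and Y the inner pair one step 3' on the
# top strand. The table is complete over the six allowed pairs
# {AU, UA, CG, GC, GU, UG} and symmetric under duplex reversal:
# stack(p1.p2) == stack(rev(p2).rev(p1)).
#
# Loop terms are linear (base + per-nucleotide), multiloops affine
# (a + b * branches + c * unpaired, the closing helix counted as a branch).
# Values for Watson-Crick stacks approximate the Turner 2004 set; wobble
# stacks are coarser. The table is deliberately small so that exhaustive
# structure enumeration remains an exact cross-check; drop-in replacement
# with a fuller parameter set only requires editing this file.

version = "reduced-nn-1"

[loops]
hairpin_base = 4.5
hairpin_per_nt = 0.3
internal_base = 2.0
internal_per_nt = 0.4
bulge_base = 3.5
bulge_per_nt = 0.4
min_hairpin = 3
max_loop = 30

[multiloop]
a = 3.4
b = 0.4
c = 0.1

[stacks]
"AU.AU" = -0.93
"AU.UA" = -1.10
"AU.CG" = -2.24
"AU.GC" = -2.08
"AU.GU" = -0.80
"AU.UG" = -1.00
"UA.AU" = -1.33
"UA.UA" = -0.93
"UA.CG" = -2.35
"UA.GC" = -2.11
"UA.GU" = -0.80
"UA.UG" = -0.60
"CG.AU" = -2.11
"CG.UA" = -2.08
"CG.CG" = -3.26
"CG.GC" = -2.36
"CG.GU" = -1.40
"CG.UG" = -2.10
"GC.AU" = -2.35
"GC.UA" = -2.24
"GC.CG" = -3.42
"GC.GC" = -3.26
"GC.GU" = -1.50
"GC.UG" = -2.50
"GU.AU" = -0.60
"GU.UA" = -1.00
"GU.CG" = -2.50
"GU.GC" = -2.10
"GU.GU" = -0.50
"GU.UG" = 0.50
"UG.AU" = -0.80
"UG.UA" = -0.80
"UG.CG" = -1.50
"UG.GC" = -1.40
"UG.GU" = -0.60
"UG.UG" = -0.50
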