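# osteomorph

Micro-CT long-bone region delimitation and 3D bone morphometry.

Quantitative bone studies in small animals — growth, ageing, disuse and
spaceflight osteopenia — depend on where the regions of interest are drawn.
The epiphysis+metaphysis (EM) zones and the diaphysis of a long bone have
different architecture and respond differently to loading, yet their
boundaries are usually placed by eye from anatomical landmarks, which makes
results hard to compare between laboratories.  `osteomorph` implements a
reproducible, numerical delimitation of the basic regions of a long bone
from a reconstructed micro-CT volume, the standard 3D morphometric
parameter set per region, and the group-comparison statistics used in this
field.  It is aimed at researchers processing micro-CT stacks of rodent
long bones (the defaults are scaled to the gerbil humerus) and is validated
end to end on synthetic bone phantoms with known ground truth.

## The delimitation algorithm

The bone (axis 0 of the stack, proximal end first) is virtually transected
into 100 µm transverse sections and the mean linear attenuation of
*cortical* bone, µ.Ct_i, is computed per section.  The percent change
between adjacent sections,

    Variation_i = 100 · (µ.Ct_i − µ.Ct_{i−1}) / µ.Ct_{i−1}   [%],

is near zero along the diaphysis, where cortical density is uniform, and
exceeds 1 % per section in the EM-zones, where mineral density ramps toward
the bone ends.  The diaphysis is recovered as the maximal sustained run of
sections with |Variation| ≤ 1 %; the flanking faces are the region
borderlines, reported also as offsets from the bone ends in % of sample
length.  A second pass splits the diaphysis at the change point of the
sectionwise cancellous volume fraction (Cn.BV/Sc.V) into a proximal zone A,
nearly free of trabeculae, and a distal zone B.

Per region the package reports the standard parameter set: Sa.Le, TV, BV,
BV/TV, median attenuations µ.B/µ.Ct/µ.Cn, Ct.BV/TV, Cn.BV/Sc.V, Sc.V,
model-independent Tb.Th/Tb.Sp/Tb.N (maximal-inscribed-sphere local
thickness), and the mid-diaphysis cross-section Tt.Ar, Ct.Ar, Ct.Ar/Tt.Ar
and distance-transform Ct.Th.

## Worked example

```python
from osteomorph import default_gerbil_spec, generate_phantom, segment_volume, delimit

volume, truth = generate_phantom(default_gerbil_spec(voxel_um=36.0))
labels, threshold = segment_volume(volume)      # Otsu + cortical/cancellous split
seg, profile, variation = delimit(volume, labels)
print(seg.prox_offset_pct, seg.dist_offset_pct)
```

On the default phantom (15.9 mm humerus-scale bone, boundaries planted at
18.5 % and 15.6 % of length) this prints offsets `19.0` and `15.2` — both
within one 108 µm section of the planted planes.  The full report
(`examples/03_morphometry.py`) recovers the phantom's generative values:

```
Dia Ct.BV/TV = 0.760  (generative value 0.759)
Tb.Th = 74 um  (planted rod thickness 72 um)
mid-diaphysis: Tt.Ar = 1.22 mm^2 (analytic 1.23), Ct.Ar = 0.97 mm^2 (analytic 0.98)
Ct.Th = 346 um (generative 344 um)
```

i.e. volume fractions to well under 2 % relative and thickness metrics to
about one voxel.  The `examples/` directory has one short script per
capability (phantom generation, delimitation, morphometry, group
comparison); a thin CLI (`osteomorph phantom|segment|delimit|morpho|compare|run`)
wraps the same functions for shell use.

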