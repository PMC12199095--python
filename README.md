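# cnc-cslabel

Atomistic models of Cs-labeled cellulose nanocrystals (CNCs), incoherent
Z-contrast STEM image simulation, and the interatomic statistics that
connect measured micrographs back to candidate crystal habits.

## The problem

Sulfuric-acid-hydrolyzed CNCs carry surface sulfate half-esters whose
counterions can be exchanged for Cs⁺ (Z = 55). In annular dark-field STEM,
where intensity scales roughly as Z^1.7, each Cs⁺ is a bright point marker
for one sulfate group — and therefore for one surface C6 position of a
cellulose chain. The spacings between Cs spots (along the chain axis and
between parallel "Cs lines") are fingerprints of the crystal cross-section:
an 18/24-chain elementary fibril with a **diamond** habit (bounded by
{110}/{1-10} facets) predicts different projected spacings than a
**rectangular** habit (bounded by {200}/{010}). This package builds the
full computational route:

```
lattice -> decoration -> substrate -> imaging -> detection -> analysis
   |            |            |           |            |           |
 Iβ cell,   sulfate/Cs   amorphous-C  Z^1.7 PSF    3x3 mean,   RDF, row
 18/24-     arms on      support     rendering,   threshold/  grouping,
 chain      surface C6   slab        shot noise   RF pixel    Gaussian
 habits     sites                                 classifier, peak fits,
                                                  centroids   model ranking
```

plus a `synthetic_data` module that generates complete micrographs with
ground truth, so every stage is quantitatively testable.

## The geometry at the core

Cellulose Iβ is monoclinic (a = 7.784 Å, b = 8.201 Å, c = 10.380 Å,
γ = 96.5°, chain axis ∥ c; two chains per cell related by a (a+b)/2
centering with a c/4 axial stagger; a two-fold screw along each chain).
From these constants alone follow the printed observables:

| quantity | expression | value |
|---|---|---|
| sheet (interlayer) spacing | d(200) = a·sin γ / 2 | 3.9 Å |
| same-facet C6 repeat along a chain | c | 10.4 Å |
| chain rows, {1-10}-type face | ‖a+b‖/2 | 5.3 Å |
| chain rows, {110}-type face | ‖a−b‖/2 | 6.0 Å |
| chain rows, (200) sheet | ‖b‖ | 8.2 Å |
| chain rows, (010) face | ‖a‖ | 7.8 Å |

In a face-on projection the c/4 stagger of the two chain sublattices
splits the along-axis nearest-neighbor Cs spacings of the rectangular
habit into {c/4, 3c/4} = {2.6, 7.8} Å, while the diamond habit's decorated
{110} faces give a uniform c/2 = 5.2 Å — inside the experimentally
observed 3–7 Å window, which is the basis of the habit discrimination.

## Worked example

The analytic projected Cs spacings of fully decorated face-on models:

```sh
$ cnc-cslabel compare --habit diamond --chains 24 --repeats 4
along-axis (A, count): [(5.19, 28)]
inter-line (A, count): [(5.964479648920135, 3)]

$ cnc-cslabel compare --habit rectangular --chains 24 --repeats 4
along-axis (A, count): [(2.5950000000000024, 16), (7.7849999999999975, 12)]
inter-line (A, count): [(7.783999999999999, 3)]
```

Reading: the diamond model puts Cs rows 5.96 Å apart with a 5.19 Å repeat
along the axis; the rectangular model puts rows 7.78 Å apart with
alternating 2.6 / 7.8 Å along-axis gaps. Against measured spacings of
3–7 Å (along) and 6–7 Å (between lines), the diamond model scores a far
smaller mean absolute mismatch — `compare_models` ranks it first.

The full synthetic experiment (build → decorate → render with shot noise
on a 2 nm carbon film → detect → measure → rank) runs as

```sh
cnc-cslabel run --config config.yaml   # or: python -m cnc_cslabel.cli run ...
```

with a YAML pipeline config (all stages have defaults; see
`cnc_cslabel.pipeline.PipelineConfig`). On the default configuration the
detection stage recovers every planted Cs (recall 1.0, localization error
below 10 pm) and the comparison table ranks `diamond-24` above
`rectangular-24`.

## Layout

- `src/cnc_cslabel/lattice.py` — Iβ cell, habits, facets, surface C6 sites
- `src/cnc_cslabel/decoration.py` — sulfate/Cs arms, conformer rules, occupancy
- `src/cnc_cslabel/substrate.py` — random amorphous-carbon support
- `src/cnc_cslabel/imaging.py` — Z^1.7 Gaussian-PSF renderer, Poisson noise
- `src/cnc_cslabel/detection.py` — smoothing, pixel classification, centroids
- `src/cnc_cslabel/analysis.py` — RDF, profile spacings, row grouping, ranking
- `src/cnc_cslabel/synthetic_data.py` — ground-truth scenes and fixtures
- `src/cnc_cslabel/pipeline.py`, `cli.py` — configured pipeline and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
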