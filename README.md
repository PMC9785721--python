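# ramanmix

Gray-box analysis of in-vivo skin Raman spectra: constrained MCR-ALS spectral
unmixing with SIMPLISMA initialization, the surrounding preprocessing, and
classification of the resolved concentration profiles — all testable against
a synthetic skin-Raman generator with known ground truth.

## What's inside

| module | purpose |
| --- | --- |
| `ramanmix.synthetic` | Skin-like Raman dataset generator: a 4-component pure-spectrum library (melanin, proteins, water, NMF+lipids), class-dependent concentrations for the 5-class cohort (NS/K/BCC/MM/PN, 540/113/122/67/158), fluorescence background, CCD-etalon ripple, and noise calibrated to a target SNR (default 3). |
| `ramanmix.preprocess` | nm ↔ cm⁻¹ axis conversion, range cropping, asymmetric-least-squares baseline removal (λ=10⁶, p=0.1, 10 iterations), Savitzky–Golay smoothing (window 15, order 1), min-max rescaling. |
| `ramanmix.rank` | SVD scree scan with two component-count heuristics (largest consecutive drop; count above a relative floor). |
| `ramanmix.mcr` | Constrained MCR-ALS: D = C·Sᵀ + E with exact NNLS non-negativity, equal-spectral-area closure (scale absorbed into C), equality-constrained fixed spectra (NaN-sentinel rows), SIMPLISMA initialization (10 % allowed noise), 150-iteration cap, 0.1 % residual-SD convergence, divergence detection, lack-of-fit / explained-variation metrics. |
| `ramanmix.classify` | ROC/AUC (Mann–Whitney with midrank ties) with DeLong 95 % CI, unregularized binary logistic regression with Wald p-values, PLS-DA with stratified 10-fold CV, box-plot summaries, and the standard contrast battery (BCC vs rest, BCC vs MM, malignant vs benign, MM vs PN / K+PN). |
| `ramanmix.pipeline` | Three reproducible scenario presets: `raw_unmix_9` (250 raw spectra, 9 components), `preprocessed_sweep_4_30` (cohort, component sweep), `basis_constrained_8` (8 components, 4 fixed to the known basis, plus the classification battery). Manifests carry SHA-256 checksums; seeded reruns are byte-identical. |

## CLI

```bash
ramanmix simulate --seed 1 --snr 3 --out data/
ramanmix preprocess data/spectra.csv --crop 1114:1874 \
    --asls lam=6,p=0.1,iters=10 --savgol w=15,o=1,d=0 --out data/preprocessed.csv
ramanmix rank data/preprocessed.csv --max 30
ramanmix unmix data/preprocessed.csv --components 8 --basis basis.csv \
    --max-iter 150 --tol 0.1 --noise 10 --out results/
ramanmix classify results/C.csv data/labels.csv --out report.json
ramanmix run --scenario basis_constrained_8 --seed 1 --out runs/basis8
```

Spectra CSVs are wide format: first column `sample_id`, remaining column
headers the axis values in decimal cm⁻¹ (or nm). Basis CSVs contain one row
per component; rows for free components are left empty (NaN sentinel).

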