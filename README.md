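# nlmdct — DCT-subspace nonlocal-means denoising for magnitude MR images

Magnitude MR images carry Rician noise: the modulus of a complex signal
whose real and imaginary channels are corrupted by independent Gaussian
noise of standard deviation σ.  This package implements a family of
patch-based filters for such images, for researchers who need a tested,
reproducible reference implementation of:

* **NLM** — the classic nonlocal-means estimator

  û(i) = Σ_{j∈Sᵢ} w(i,j) v(j),   w(i,j) = exp(−‖p(Nᵢ)−p(Nⱼ)‖² / h²) / Z(i),

  where p(Nᵢ) is the r×r patch around pixel i, Sᵢ an S×S search window,
  h the smoothing bandwidth and Z(i) the normaliser;

* **NLM-DCT** — the same estimator with the patch distance measured on the
  first *d* coefficients of the patch's orthonormal 2-D DCT, taken in JPEG
  zigzag order.  Low-frequency DCT coefficients concentrate patch energy, so
  a small subspace gives less noisy similarity weights; by Parseval's
  identity, d = M = r² reproduces plain NLM exactly;

* **UNLM / UNLM-DCT** — either filter followed by Rician bias correction.
  The squared magnitude obeys E[v²] = u² + 2σ², so the filtered value is
  corrected as û ← √(max(û² − 2σ², 0)).

It also ships a Rician noise simulator with the percent-of-brightest-tissue
level convention (level L% ⇒ σ = (L/100)·t), a background σ estimator
(σ̂ = √(mean v²/2) over signal-free pixels), MSE/PSNR/residual evaluation, a
deterministic piecewise-constant brain phantom generator, and a CLI.

## Worked example

```sh
$ nlmdct phantom --preset T1 --height 64 --width 64 clean.pgm
phantom T1 64x64 t=150 -> clean.pgm
$ nlmdct addnoise --level 9 --t 150 --seed 1 clean.pgm noisy.pgm
addnoise sigma=13.5 seed=1 -> noisy.pgm
$ nlmdct denoise --method unlm-dct --h 50 --d 10 --sigma 13.5 \
    --clean clean.pgm noisy.pgm denoised.tiff
mse=45.7432 psnr=29.1079 dB
denoise method=unlm-dct h=50 d=10 done
```

The phantom is a piecewise-constant brain-like image whose brightest tissue
is t = 150; 9% noise therefore means σ = 13.5.  The UNLM-DCT run (patch
5×5, window 11×11, d = 10 of 25 coefficients) raises PSNR from 21.44 dB
(noisy, printed by `nlmdct evaluate`) to 29.11 dB; PSNR here uses
Max = max(clean, noisy) as its peak.

The benchmark harness tunes h per method over a grid and compares all
methods on one shared noise realisation:

```sh
$ nlmdct benchmark --levels 9,15 --methods nlm,unlm,unlm-dct --t 150 --seed 1 clean.pgm
     image  level_percent   method          h    d        mse   psnr_db  seed
 clean.pgm            9.0    noisy        NaN  NaN 266.975708 21.437835     1
 clean.pgm            9.0      nlm  76.367532  NaN 182.090802 23.099672     1
 clean.pgm            9.0     unlm  76.367532  NaN  47.213506 28.961890     1
 clean.pgm            9.0 unlm-dct  48.299068 10.0  45.358052 29.136008     1
 ...
```

showing the characteristic ordering UNLM-DCT ≥ UNLM ≥ NLM > noisy.
`nlmdct sweep-d` plots PSNR against the subspace dimension d and reports
the optimum `d_opt`, which moves to small d as noise grows.

Published parameter tables sometimes write h as `base^exponent`; the CLI
and config files accept that notation (`--h 3^4.38` ⇒ h = 122.9677).

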