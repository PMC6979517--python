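# vancittert

Iterative Van Cittert image restoration with decoupled, plug-in denoising —
a library and CLI for deconvolving blurred, noisy 2-D grayscale images such
as optical-microscopy frames.

## The problem and the method

An imaging system observes `J = P I + N`: the true scene `I` blurred by the
point spread function (PSF) `P` plus additive white noise `N`. Minimising
the residual `‖J − P I‖²` directly is ill-posed — `P` always has small
eigenvalues, and inverting through them amplifies the noise without bound.

The method iterates the classical Van Cittert update

```
I_k = I_{k−1} + β Pᵀ (J − P I_{k−1}),
```

a steepest-descent step on the residual, and interleaves an independent
noise-reduction operator `R_N`: every `s`-th iterate (or, in automated mode,
whenever the iterate's estimated noise level crosses a threshold σ_thr) is
replaced by its denoised version. Deblurring and denoising stay fully
decoupled, so any denoiser satisfying the admissibility condition

```
R_N(I + N) = I + o(N),   Var(o(N)) ∝ Δ σ²,   Δ ≪ 1
```

plugs in unchanged. Because circular convolution is diagonal in the Fourier
basis, the iterate splits exactly into a structure term
`D_k = Σ_uv (1 − (1 − β|ζ_uv|²)^k)(I, Z_uv) Z_uv` and a noise term with
per-frequency gain `F_k = (1 − (1 − β|ζ_uv|²)^k)/ζ_uv`. Consecutive gains
obey `1 ≤ F_k/F_{k−1} < 2`, which is what lets an admissible denoiser hold
the residual noise variance at the order of `Δσ²` while the structure term
converges to the truth. The package ships this error analysis as executable
diagnostics and uses it as the exact oracle for its own engine.

Provided denoisers: orthogonal wavelet soft-thresholding (default; its
reduction factor is `Δ = (2 log RC + 1)(log RC + 1)/RC`), a thin adapter to
an external BM3D implementation (`pip install bm3d`; the benchmark strength
σ = 7.5 and per-scenario intervals s ∈ {85, 25, 550, 10, 50, 5} are built
in), and identity/zero controls. Six benchmark degradation scenarios
(Cauchy-profile 15×15, 9×9 uniform, 5×5 binomial and Gaussian PSFs with
noise variances from 0.3 to 64) are reproduced by the simulator.

## Worked example

```
$ vancittert simulate --scenario 5 --size 128 --seed 7 --out demo
$ vancittert restore demo/observation.png --scenario 5 --out demo/restored.png
INFO ran 1200 iterations, 240 denoise events
$ vancittert evaluate demo/truth.png demo/observation.png
{"psnr_db": 34.1921, "ssim": 0.941229}
$ vancittert evaluate demo/truth.png demo/restored.png
{"psnr_db": 38.9733, "ssim": 0.959575}
$ vancittert restore demo/observation.png --scenario 5 --auto --out demo/auto.png
$ vancittert evaluate demo/truth.png demo/auto.png
{"psnr_db": 39.896, "ssim": 0.978873}
```

`simulate` writes a synthetic microscopy-like ground truth and its
scenario-5 degradation (Gaussian blur, std 1.6, noise variance 4).
Restoration with defaults lifts quality by 4.8 dB PSNR over the observation;
`--auto` replaces the fixed (σ, s) schedule with the noise-threshold trigger
and needs no manual parameters. Each `restore` also writes a JSON manifest
sufficient to replay the run bit-for-bit.

The same pipeline is available as a library:

```python
import vancittert as vc

truth = vc.synth_image(vc.FixtureSpec(kind="blobs", size=(128, 128), seed=7))
scn = vc.build_scenario(5)
obs = vc.degrade(truth, scn.make_psf(), scn.noise_variance, seed=7)
result = vc.restore(obs, scn.make_psf(), vc.scenario_config(5))
print(vc.psnr(truth, result.restored), result.denoise_events[:3])
```

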