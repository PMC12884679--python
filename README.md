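# retinograph

Retinal fundus analysis pipeline: vessel segmentation with a residual
U-Net, artery/vein classification with a graph convolutional network over
the 8-connected vessel pixel graph, vessel calibre morphometry
(CRAE / CRVE / AVR) and hypertensive-retinopathy grading from the
arteriovenous ratio.  A synthetic fundus generator with exact ground
truth (masks, A/V labels, per-pixel widths, true calibres) makes every
stage testable offline, with no dataset downloads.

The neural networks are implemented on a small NumPy reverse-mode
autodiff core (`retinograph.nn`) — no deep-learning framework is
required — and train to useful accuracy on the synthetic task in well
under a minute on one CPU.

## Layout

| Module | Purpose |
| --- | --- |
| `retinograph.synthetic` | vessel-tree generator, rasteriser, healthy/hr presets |
| `retinograph.preprocessing` | green-channel extraction, histogram equalisation, CLAHE, denoising, joint augmentation |
| `retinograph.segmentation` | residual U-Net (dilated-fusion bottleneck, summation skips), BCE training, prediction, binarisation |
| `retinograph.graph` | 8-connected self-looped pixel graph, symmetric adjacency normalisation, node features |
| `retinograph.gcn` | GCN artery/vein node classifier, Dice + cross-entropy training |
| `retinograph.morphometry` | skeletonisation, perpendicular width measurement, CRAE/CRVE/AVR |
| `retinograph.grading` | AVR → HR grade → binary normal/HR decision |
| `retinograph.evaluation` | confusion-matrix metrics, ROC/AUC, Dice |
| `retinograph.pipeline`, `retinograph.cli`, `retinograph.io` | orchestration, CLI, readers/writers |

## CLI

All stages are subcommands of a single entry point:

```sh
retinograph synth --n 5 --seed 1 --preset healthy --out data/
retinograph preprocess --input data/sample_0001/image.png --out enhanced.png
retinograph train-seg --data data/ --out seg.npz --epochs 10
retinograph segment --model seg.npz --input data/sample_0001/image.png --out segout/
retinograph graph --mask segout/mask.png --out graphout
retinograph train-av --data data/ --out gcn.npz
retinograph classify --model gcn.npz --mask segout/mask.png \
    --image data/sample_0001/image.png --out av_pred.png
retinograph measure --mask segout/mask.png --labels av_pred.png \
    --disc-center 128,128 --disc-radius 20 --formula-mode canonical \
    --micron-per-pixel 15 --out calibres.json
retinograph grade --avr 0.65
retinograph evaluate --pred segout/mask.png --truth data/sample_0001/mask.png \
    --out metrics.json
retinograph pipeline --preset hr --seed 0 --out run/   # end to end
```

The `hr` preset narrows arteries and dilates veins so the measured AVR
falls in the hypertensive band (&lt; 0.5); `healthy` sits near 0.67.

Calibre formulas come in two modes: `paper` evaluates the combination
formulas exactly as printed in the source reference; `canonical` uses the
classical square-root Parr–Hubbard forms, which produce clinically
plausible magnitudes when diameters are converted to micrometres
(`--micron-per-pixel`).

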