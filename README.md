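# pvlkit

Multi-modal prediction of residual ≥moderate paravalvular leak (PVL) after
transcatheter aortic valve implantation in bicuspid aortic valve patients —
a 3D CNN imaging branch over CT + segmentation masks, a clinical MLP, and
cross-attention fusion ("Model B"), compared against a conventional
35-feature tabular baseline ("Model A"), with a complete statistical
evaluation harness. Everything is exercisable end-to-end on synthetic
aortic-root CT phantoms; no external data are required.

Because the target environment ships without a deep-learning framework, the
network stack (reverse-mode autograd, 3D convolutions, batch norm, Adam,
plateau scheduling) is implemented in NumPy under `pvlkit.nnx` and verified
against loop oracles.

## Layout

| module | role |
| --- | --- |
| `pvlkit.phantom` | synthetic aortic-root CT phantoms, co-registered masks, clinical tables with a known logistic outcome model |
| `pvlkit.preprocess` | resample → window [−79, 304] → foreground crop (margin 30) → resize → random 64³/32³ patches |
| `pvlkit.nnx` | NumPy autograd + layers + optimizers |
| `pvlkit.model_b` | 3D ResNet-18 encoder, clinical MLP, cross-attention fusion, sigmoid head, BCE |
| `pvlkit.training` | Stage-1 proxy pretraining (calcification-volume regression, label-free by construction), Stage-2 5-fold stratified fine-tuning with out-of-fold predictions |
| `pvlkit.model_a` | 35-feature baseline: LR-L1/LR-L2/MLP/RF/GBM, class-balanced, winner by CV AUC |
| `pvlkit.evaluate` | AUC (Mann–Whitney), confusion metrics, fold aggregation with dual CI conventions, DeLong test, Brier + calibration, decision curves, cohort-table tests (Wilcoxon / chi-square-Yates / Fisher) |
| `pvlkit.explain` | 3D Grad-CAM over the final encoder stage, overlay export |

## CLI

```bash
pvlkit simulate --n 210 --event-rate 0.1667 --seed 0 --out-dir cohort/
pvlkit pretrain --cohort-dir pretrain_cohort/ --out ckpt/encoder.npz
pvlkit train    --cohort-dir cohort/ --encoder ckpt/encoder.npz --out runB/
pvlkit baseline --cohort-dir cohort/ --folds runB/folds.json --out runA/
pvlkit evaluate --oof-a runA/oof_predictions.csv --oof-b runB/oof_predictions.csv --out report/
pvlkit cohort-table --clinical cohort/clinical.csv --out table1.csv
pvlkit explain  --model runB/fold0.npz --cohort-dir cohort/ --case <patient_id> --out cam/
```

All commands default to the desk-scale profile (1/8-width encoder, 64×48×32
volumes, 32³ patches) so they finish in minutes on a CPU; `--full-scale`
switches to the published geometry (192×128×96, 64³ patches, full schedules).

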