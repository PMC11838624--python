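# survbit

Cost-optimal intervention policies for binary time-series surveillance of a
hidden two-state system.

The monitored system (a device, a patient, a population) is a hidden Markov
chain alternating between a *normal* and an *abnormal* state. A noisy binary
detector emits one bit per time step. Each step you may intervene at a
normalized cost `K`, or do nothing and pay 1 whenever the system is abnormal;
running surveillance with an `n`-bit observation window costs `S[n]` per
step. `survbit` computes, exactly:

- joint/posterior probabilities of any observation history under the
  stationary chain (forward filtering, linear in window length);
- the Δ decision statistic per history (expected cost of inaction minus
  intervention) and the expected cost per unit time of any decision table;
- the optimal decision table at each depth (intervene iff Δ > 0), protocol
  selection across depths against the never/always baselines, and
  phase diagrams of the winning protocol over cost-parameter grids.

A seeded simulator reproduces every exact loss empirically and generates all
synthetic data used by the tests.

## CLI

All commands accept model parameters as flags (`--q01 --q10 --p01 --p11 --K
--S 0,0.01,...`) or via `--config model.yaml` (keys `q01 q10 p01 p11 K S`, or
raw `k`/`c`/`s` which are normalized by `c`). Strict parameter validation is
on by default; `--lenient` only enforces probability ranges.

```sh
# best protocol among no-surveillance and 1..max-n bit windows (JSON)
survbit optimize --q01 0.1 --q10 0.3 --p01 0.2 --p11 0.8 --K 0.4 --S 0,0.01 --max-n 1

# exact (and optionally simulated) cost of one strategy (TSV)
survbit evaluate --q01 0.1 --q10 0.3 --p01 0.2 --p11 0.8 --K 0.4 --S 0,0.01 \
    --strategy n=1:01 --simulate 1000000 --seed 1

# per-history joint probabilities, posterior, and delta (TSV)
survbit tabulate --q01 0.1 --q10 0.3 --p01 0.2 --p11 0.8 --K 0.4 --n 2

# simulate a run to CSV (columns t,state,obs,action,cost)
survbit simulate --q01 0.1 --q10 0.3 --p01 0.2 --p11 0.8 --K 0.4 --S 0,0.01 \
    --T 100000 --seed 7 --strategy n=1:01 --out run.csv

# winning-protocol phase diagram over a 2-D parameter grid (TSV + metadata)
survbit phase-diagram --q01 0.1 --q10 0.3 --p01 0.2 --p11 0.8 --K 0.4 --S 0,0.01 \
    --axis1 K:0:1:201 --axis2 S1:0:0.3:61 --max-n 1 --out grid.tsv
```

Strategies are written `n=<depth>:<table bits>` with table entries indexed by
the observation history read oldest bit first (so `n=2:0001` intervenes only
when the two most recent bits are both 1), or as JSON
`{"n": 2, "table": {"00": 0, "01": 0, "10": 0, "11": 1}}`.

Exit codes: 0 success, 2 invalid parameters/configuration, 1 other errors.

## Library sketch

```python
from survbit import (ModelBundle, SystemModel, DetectorModel, CostModel,
                     Strategy, expected_loss, select_protocol, run_policy)

bundle = ModelBundle(SystemModel(q01=0.1, q10=0.3),
                     DetectorModel(p01=0.2, p11=0.8),
                     CostModel(K=0.4, S=(0.0, 0.01)))
choice = select_protocol(max_n=1, bundle=bundle)
print(choice.chosen.label, choice.loss.value)   # n=1:01 0.2
```
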