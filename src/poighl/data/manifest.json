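{
 "bladder_cancer_128": {
  "n": 128,
  "units": "months",
  "source": "Remission times of 128 bladder cancer patients (Lee & Wang, Statistical Methods for Survival Data Analysis)",
  "sha256": "45830dcfde6b5b0c4a8f3ad35373a245ab59c9407e398fc44a307fc6bd83f9fb"
 },
 "mechanical_20": {
  "n": 20,
  "units": "unitless failure time",
  "source": "Failure times of 20 mechanical components (Murthy, Xie & Jiang, Weibull Models)",
  "sha256": "39f1832adcc2f3584ec7590b34913b8d13c053ed3c2e4035c45334125d53c1ec"
 },
 "software_34": {
  "n": 34,
  "units": "days",
  "source": "Intervals between successive failures of a piece of software, 34 records",
  "sha256": "b7e364c55c7c7e8d9b63dfda67652e8929310820d4655e9c80784241cfa69921"
 },
 "fibers_20mm": {
  "n": 69,
  "units": "GPa",
  "source": "Failure stresses of single carbon fibers, 20 mm gauge length (Bader & Priest)",
  "sha256": "b58ebace6e49eefaa9f66c3730f62e748a901813da2a265b2cc689db19fc585f"
 },
 "fibers_50mm": {
  "n": 65,
  "units": "GPa",
  "source": "Failure stresses of single carbon fibers, 50 mm gauge length (Bader & Priest)",
  "sha256": "fa04c341c12ee4900377de5f2ff9c5cd5dd15da91360d60498c644428754de43"
 }
}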