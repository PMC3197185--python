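# Default pathway definition: core enzymes of de novo fatty-acid synthesis,
# triacylglycerol (TAG) assembly, and their regulation in green microalgae.
# Groups are matched to enzymes by case-insensitive keyword containment
# against annotated headers; the longest matching keyword wins.
enzymes:
  - abbrev: ACCase
    full_name: acetyl-CoA carboxylase
    pathway: fatty_acid
    match_keywords: ["acetyl-coa carboxylase", "acetyl coenzyme a carboxylase"]
    ec_numbers: ["6.4.1.2"]
  - abbrev: MAT
    full_name: malonyl-CoA:ACP transacylase
    pathway: fatty_acid
    match_keywords: ["malonyl-coa:acp transacylase", "malonyl coa-acyl carrier protein transacylase"]
    ec_numbers: ["2.3.1.39"]
  - abbrev: KAS
    full_name: 3-ketoacyl-ACP synthase
    pathway: fatty_acid
    match_keywords: ["3-ketoacyl-acp synthase", "beta-ketoacyl-acp synthase", "3-oxoacyl-acp synthase"]
    ec_numbers: ["2.3.1.41"]
  - abbrev: KAR
    full_name: 3-ketoacyl-ACP reductase
    pathway: fatty_acid
    match_keywords: ["3-ketoacyl-acp reductase", "3-oxoacyl-acp reductase"]
    ec_numbers: ["1.1.1.100"]
  - abbrev: HD
    full_name: 3-hydroxyacyl-ACP dehydratase
    pathway: fatty_acid
    match_keywords: ["3-hydroxyacyl-acp dehydratase", "hydroxyacyl-acp dehydratase"]
    ec_numbers: ["4.2.1.59"]
  - abbrev: ENR
    full_name: enoyl-ACP reductase
    pathway: fatty_acid
    match_keywords: ["enoyl-acp reductase", "enoyl-acyl carrier protein reductase"]
    ec_numbers: ["1.3.1.9"]
  - abbrev: FAT
    full_name: fatty acyl-ACP thioesterase
    pathway: fatty_acid
    match_keywords: ["acyl-acp thioesterase", "fatty acyl-acp thioesterase"]
    ec_numbers: ["3.1.2.14"]
  - abbrev: ACP
    full_name: acyl carrier protein
    pathway: fatty_acid
    match_keywords: ["acyl carrier protein"]
  - abbrev: GPAT
    full_name: glycerol-3-phosphate acyltransferase
    pathway: TAG
    match_keywords: ["glycerol-3-phosphate acyltransferase"]
    ec_numbers: ["2.3.1.15"]
  - abbrev: LPAAT
    full_name: lyso-phosphatidic acid acyltransferase
    pathway: TAG
    match_keywords: ["lyso-phosphatidic acid acyltransferase", "lysophosphatidic acid acyltransferase", "1-acylglycerol-3-phosphate acyltransferase"]
    ec_numbers: ["2.3.1.51"]
  - abbrev: PAP
    full_name: phosphatidic acid phosphatase
    pathway: TAG
    match_keywords: ["phosphatidic acid phosphatase", "phosphatidate phosphatase"]
    ec_numbers: ["3.1.3.4"]
  - abbrev: LPAT
    full_name: lyso-phosphatidylcholine acyltransferase
    pathway: TAG
    match_keywords: ["lyso-phosphatidylcholine acyltransferase", "lysophosphatidylcholine acyltransferase"]
    ec_numbers: ["2.3.1.23"]
  - abbrev: DGAT
    full_name: diacylglycerol acyltransferase
    pathway: TAG
    match_keywords: ["diacylglycerol acyltransferase", "diacylglycerol o-acyltransferase"]
    ec_numbers: ["2.3.1.20"]
  - abbrev: DAGK
    full_name: diacylglycerol kinase
    pathway: TAG
    match_keywords: ["diacylglycerol kinase"]
    ec_numbers: ["2.7.1.107"]
  - abbrev: G3PDH
    full_name: glycerol-3-phosphate dehydrogenase
    pathway: TAG
    match_keywords: ["glycerol-3-phosphate dehydrogenase"]
    ec_numbers: ["1.1.1.8"]
  - abbrev: AMPK
    full_name: AMP-activated kinase
    pathway: regulatory
    match_keywords: ["amp-activated kinase", "amp-activated protein kinase"]
    ec_numbers: ["2.7.11.31"]
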