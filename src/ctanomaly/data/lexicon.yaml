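# Lexicon, certainty-cue grades, category correspondence table and report
# templates for the rule-based report information-extraction engine and the
# phantom report renderer. Surface forms are matched case-insensitively,
# longest match first, left to right. Entries starting with "re:" are
# regular expressions.

entities:
  observation:
    - nodule
    - mass
    - tumor
    - cyst
    - stone
    - calculus
    - polyp
    - wall thickening
    - fatty change
    - steatosis
    - splenomegaly
    - hydronephrosis
    - duct dilation
    - dilated duct
    - abnormality
    - lesion
    - low-density area
  clinical_finding:
    - metastasis
    - cancer
    - carcinoma
    - hepatocellular carcinoma
    - cholecystitis
    - pancreatitis
  modifier:
    location:
      - left kidney
      - right kidney
      - kidney
      - liver
      - hepatic
      - gallbladder
      - pancreas
      - pancreatic
      - spleen
      - splenic
    certainty:
      - no evidence of
      - without evidence of
      - unremarkable
      - cannot be excluded
      - cannot be ruled out
      - possible
      - may represent
      - suspicious for
      - suspected
      - is seen
      - are seen
      - is noted
      - is present
    change:
      - enlarged
      - unchanged
      - increased
      - decreased
      - new
    characteristics:
      - hypodense
      - hyperdense
      - calcified
      - cystic
      - solid
    size:
      - "re:\\d+(?:\\.\\d+)?\\s?mm"
      - "re:\\d+(?:\\.\\d+)?\\s?cm"

# Certainty cue -> ordinal grade; 0 = definite absence, 4 = definite presence.
certainty_grades:
  no evidence of: 0
  without evidence of: 0
  unremarkable: 0
  cannot be excluded: 1
  cannot be ruled out: 1
  possible: 2
  may represent: 2
  suspicious for: 3
  suspected: 3
  is seen: 4
  are seen: 4
  is noted: 4
  is present: 4

# Location surface form -> organ id (null = route by laterality rule).
locations:
  liver: liver
  hepatic: liver
  gallbladder: gallbladder
  pancreas: pancreas
  pancreatic: pancreas
  spleen: spleen
  splenic: spleen
  left kidney: kidney_L
  right kidney: kidney_R
  kidney: null   # no laterality -> both sides

# Finding word -> disease category, per organ. Words absent for an organ
# are recorded as unmapped and fall into the "other" category.
categories:
  liver:
    mass: mass
    nodule: mass
    tumor: mass
    lesion: mass
    low-density area: mass
    metastasis: mass
    cancer: mass
    carcinoma: mass
    hepatocellular carcinoma: mass
    cyst: cyst
    fatty change: fatty_change
    steatosis: fatty_change
  gallbladder:
    stone: stone
    calculus: stone
    polyp: polyp
    wall thickening: wall_thickening
    cholecystitis: wall_thickening
  pancreas:
    mass: mass
    nodule: mass
    tumor: mass
    lesion: mass
    cancer: mass
    carcinoma: mass
    metastasis: mass
    cyst: cyst
    duct dilation: duct_dilation
    dilated duct: duct_dilation
  spleen:
    mass: mass
    nodule: mass
    tumor: mass
    lesion: mass
    metastasis: mass
    splenomegaly: splenomegaly
  kidney:
    mass: mass
    nodule: mass
    tumor: mass
    lesion: mass
    cancer: mass
    carcinoma: mass
    metastasis: mass
    cyst: cyst
    stone: stone
    calculus: stone
    hydronephrosis: hydronephrosis

# Phantom organ id -> surface form used in rendered reports.
organ_phrases:
  liver: liver
  gallbladder: gallbladder
  pancreas: pancreas
  spleen: spleen
  kidney_L: left kidney
  kidney_R: right kidney

# Category -> finding word used when the phantom renders a report.
finding_words:
  mass: mass
  cyst: cyst
  stone: stone
  polyp: polyp
  wall_thickening: wall thickening
  fatty_change: fatty change
  duct_dilation: duct dilation
  splenomegaly: splenomegaly
  hydronephrosis: hydronephrosis
  other: abnormality

# Sentence templates per certainty grade; {finding} and {organ} are filled in.
templates:
  0: "No evidence of {finding} in the {organ}."
  1: "{finding} in the {organ} cannot be excluded."
  2: "Possible {finding} in the {organ}."
  3: "Suspected {finding} in the {organ}."
  4: "A {finding} is seen in the {organ}."
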