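# Kinship surface terms -> normalized family-member name.
# Only first- and second-degree relatives of the patient are listed;
# spouse/nephew/niece and in-laws are deliberately absent (out of task scope).
terms:
  father: Father
  dad: Father
  daddy: Father
  papa: Father
  mother: Mother
  mom: Mother
  mommy: Mother
  mama: Mother
  parent: Parent
  parents: Parent
  brother: Brother
  brothers: Brother
  sister: Sister
  sisters: Sister
  sibling: Sibling
  siblings: Sibling
  son: Son
  sons: Son
  daughter: Daughter
  daughters: Daughter
  child: Child
  children: Child
  kid: Child
  kids: Child
  grandfather: Grandfather
  grandfathers: Grandfather
  grandpa: Grandfather
  granddad: Grandfather
  grandmother: Grandmother
  grandmothers: Grandmother
  grandma: Grandmother
  granny: Grandmother
  grandparent: Grandparent
  grandparents: Grandparent
  uncle: Uncle
  uncles: Uncle
  aunt: Aunt
  aunts: Aunt
  aunty: Aunt
  auntie: Aunt
  cousin: Cousin
  cousins: Cousin

# Re-normalization of a kin term possessed by another family member:
# (context normalized name, target normalized name) -> name relative to the
# patient, e.g. the patient's mother's sister is the patient's Aunt.
# Pairs whose composition leaves the annotated name set (e.g. a sibling's
# son = nephew) are intentionally missing.
composition:
  Mother:
    Sister: Aunt
    Brother: Uncle
    Mother: Grandmother
    Father: Grandfather
    Parent: Grandparent
    Son: Brother
    Daughter: Sister
    Child: Sibling
  Father:
    Sister: Aunt
    Brother: Uncle
    Mother: Grandmother
    Father: Grandfather
    Parent: Grandparent
    Son: Brother
    Daughter: Sister
    Child: Sibling
  Parent:
    Sister: Aunt
    Brother: Uncle
    Mother: Grandmother
    Father: Grandfather
    Parent: Grandparent
    Son: Brother
    Daughter: Sister
    Child: Sibling
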