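C1000001|ENG|MSH|D1000001|Myocardial Infarction|Y
C1000001|ENG|MSH|D1000001|heart attack|N
C1000001|GER|MSH|D1000001|Herzinfarkt|N
C1000001|SPA|MSH|D1000001|ataque al corazón|N
C1000001|FRE|MSH|D1000001|infarctus du myocarde|N
C1000001|ITA|MSH|D1000001|infarto miocardico|N
C1000002|ENG|MSH|D1000002|Hemophilia|Y
C1000002|GER|MSH|D1000002|Hämophilie|N
C1000002|SPA|MSH|D1000002|Hemofilia|N
C1000003|ENG|MSH|D1000003|Hemophilia A|Y
C1000003|GER|MSH|D1000003|Hämophilie A|N
C1000004|ENG|MSH|D1000004|Hemophilia B|Y
C1000004|GER|MSH|D1000004|Hämophilie B|N
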