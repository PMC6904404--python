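<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>31000001</PMID>
      <Article>
        <ArticleTitle>Outcomes of multicentre replacement therapy in severe haemophilia</ArticleTitle>
        <Journal>
          <JournalIssue>
            <PubDate>
              <Year>2018</Year>
              <Month>September</Month>
              <Day>15</Day>
            </PubDate>
          </JournalIssue>
        </Journal>
        <AuthorList>
          <Author>
            <LastName>Aldercroft</LastName>
            <ForeName>Alba</ForeName>
            <AffiliationInfo>
              <Affiliation>Institute of Cardiology, University of Leeds, Leeds LS184AB, United Kingdom</Affiliation>
            </AffiliationInfo>
          </Author>
          <Author>
            <LastName>Birchwald</LastName>
            <ForeName>Boris</ForeName>
            <AffiliationInfo>
              <Affiliation>Department of Haematology, Berlin, Germany</Affiliation>
            </AffiliationInfo>
          </Author>
          <Author>
            <LastName>Cedergren</LastName>
            <ForeName>Clara</ForeName>
            <AffiliationInfo>
              <Affiliation>Laboratory of Medicine, Springfield</Affiliation>
            </AffiliationInfo>
          </Author>
          <Author>
            <LastName>Dunholm</LastName>
            <ForeName>Dmitri</ForeName>
          </Author>
          <Author>
            <LastName>Elmqvist</LastName>
            <ForeName>Elena</ForeName>
            <AffiliationInfo>
              <Affiliation>Unidad de Hematología, Madrid, Spain</Affiliation>
            </AffiliationInfo>
          </Author>
          <Author>
            <LastName>Fernside</LastName>
            <ForeName>Farid</ForeName>
            <AffiliationInfo>
              <Affiliation>Department of Transfusion Medicine, Berlin, Germany</Affiliation>
            </AffiliationInfo>
          </Author>
        </AuthorList>
        <DataBankList>
          <DataBank>
            <AccessionNumberList>
              <AccessionNumber>NCT01234567</AccessionNumber>
            </AccessionNumberList>
          </DataBank>
        </DataBankList>
      </Article>
      <MeshHeadingList>
        <MeshHeading>
          <DescriptorName>Hemophilia A</DescriptorName>
        </MeshHeading>
      </MeshHeadingList>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>31000002</PMID>
      <Article>
        <ArticleTitle>Registry-based follow-up after acute myocardial infarction</ArticleTitle>
        <Journal>
          <JournalIssue>
            <PubDate>
              <Year>2017</Year>
              <Month>April</Month>
              <Day>2</Day>
            </PubDate>
          </JournalIssue>
        </Journal>
        <AuthorList>
          <Author>
            <LastName>Glenmore</LastName>
            <ForeName>Greta</ForeName>
            <AffiliationInfo>
              <Affiliation>Institute of Medical Informatics, Münster, Germany</Affiliation>
            </AffiliationInfo>
          </Author>
          <Author>
            <LastName>Hazelton</LastName>
            <ForeName>Hugo</ForeName>
            <AffiliationInfo>
              <Affiliation>Münster University Hospital, Münster 48149, Germany</Affiliation>
            </AffiliationInfo>
          </Author>
        </AuthorList>
      </Article>
      <MeshHeadingList>
        <MeshHeading>
          <DescriptorName>Myocardial Infarction</DescriptorName>
        </MeshHeading>
      </MeshHeadingList>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
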